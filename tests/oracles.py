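"""Independent brute-force oracles used by the test suite.

These deliberately use plain Python loops and direct linear-algebra solves so
they share no code path with the package implementation they check.
"""

import itertools

import numpy as np


def brute_pairwise(seqs):
    """(D, C) by looping over every pair and every site."""
    called = "ACGT"
    n = len(seqs)
    D = np.zeros((n, n), dtype=int)
    C = np.zeros((n, n), dtype=int)
    for i in range(n):
        C[i, i] = sum(b in called for b in seqs[i])
        for j in range(i + 1, n):
            d = c = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in called and b in called:
                    c += 1
                    d += a != b
            D[i, j] = D[j, i] = d
            C[i, j] = C[j, i] = c
    return D, C


def brute_variable_sites(seqs):
    count = 0
    for col in zip(*seqs):
        bases = {b for b in col if b in "ACGT"}
        if len(bases) >= 2:
            count += 1
    return count


def amova_ems_oracle(D, reef, region_of_reef):
    """Three-level AMOVA components via explicit loops and a 3x3 solve.

    D: squared-distance matrix; reef: reef index per colony; region_of_reef:
    region index per reef.  Returns (sigma_a, sigma_b, sigma_c).
    """
    reef = list(reef)
    region_of_reef = list(region_of_reef)
    N = len(reef)
    reefs = sorted(set(reef))
    regions = sorted(set(region_of_reef))
    P, G = len(reefs), len(regions)
    region = [region_of_reef[reefs.index(r)] for r in reef]

    def ss(indices):
        total = 0.0
        for a, b in itertools.combinations(indices, 2):
            total += D[a][b]
        return total / len(indices)

    everyone = list(range(N))
    ss_total = ss(everyone)
    ss_within = sum(ss([i for i in everyone if reef[i] == r]) for r in reefs)
    ss_by_region = sum(ss([i for i in everyone if region[i] == g]) for g in regions)
    ssd = [ss_total - ss_by_region, ss_by_region - ss_within, ss_within]
    df = [G - 1, P - G, N - P]

    n_p = {r: sum(1 for x in reef if x == r) for r in reefs}
    N_g = {g: sum(1 for x in region if x == g) for g in regions}
    sum_np2_over_Ng = sum(
        sum(n_p[r] ** 2 for r in reefs if region_of_reef[reefs.index(r)] == g) / N_g[g]
        for g in regions
    )
    n1 = (N - sum_np2_over_Ng) / df[1]
    n2 = (sum_np2_over_Ng - sum(v**2 for v in n_p.values()) / N) / df[0]
    n3 = (N - sum(v**2 for v in N_g.values()) / N) / df[0]

    MS = [ssd[0] / df[0], ssd[1] / df[1], ssd[2] / df[2]]
    A = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    return tuple(np.linalg.solve(A, np.array(MS)))


def enumerate_null(group_labels, reef_labels, statistic):
    """Exact permutation-null moments by enumerating every reef relabelling.

    Iterates all len(reef_labels)! orderings (duplicates included, which
    weights multiset permutations uniformly) and returns (mean, var, values).
    """
    values = []
    for perm in itertools.permutations(reef_labels):
        values.append(statistic(group_labels, list(perm)))
    values = np.array(values, dtype=float)
    return values.mean(), values.var(), values


def brute_pair_count(group_labels, reef_labels):
    """Same-reef same-group unordered pairs, by direct pair loop."""
    count = 0
    n = len(group_labels)
    for i in range(n):
        for j in range(i + 1, n):
            if (
                group_labels[i] == group_labels[j]
                and group_labels[i] > 0
                and reef_labels[i] == reef_labels[j]
            ):
                count += 1
    return count
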