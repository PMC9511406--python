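"""Frozen 1% critical-value tables for the laboratory consistency tests.

Cochran's maximum-variance test uses the exact union-bound construction
through the F distribution at level alpha/p; the single Grubbs test uses the
two-sided t construction at level alpha/(2p). Both reproduce the published
ISO 5725-2 1% tables to their printed precision (e.g. Cochran p=7, n=3:
0.664; Grubbs p=7: 2.139). Lookup is exact: p or n outside the table is an
error, never interpolated.
"""

# Cochran C, 1% level, keyed by (number of labs p, replicates per lab n)
COCHRAN_1PCT = {
    (2, 2): 0.9999, (2, 3): 0.9950, (2, 4): 0.9794, (2, 5): 0.9586, (2, 6): 0.9373,
    (3, 2): 0.9933, (3, 3): 0.9423, (3, 4): 0.8832, (3, 5): 0.8335, (3, 6): 0.7933,
    (4, 2): 0.9676, (4, 3): 0.8643, (4, 4): 0.7814, (4, 5): 0.7212, (4, 6): 0.6761,
    (5, 2): 0.9279, (5, 3): 0.7885, (5, 4): 0.6957, (5, 5): 0.6329, (5, 6): 0.5875,
    (6, 2): 0.8828, (6, 3): 0.7218, (6, 4): 0.6258, (6, 5): 0.5635, (6, 6): 0.5195,
    (7, 2): 0.8376, (7, 3): 0.6644, (7, 4): 0.5685, (7, 5): 0.5080, (7, 6): 0.4659,
    (8, 2): 0.7945, (8, 3): 0.6152, (8, 4): 0.5210, (8, 5): 0.4627, (8, 6): 0.4227,
    (9, 2): 0.7544, (9, 3): 0.5727, (9, 4): 0.4810, (9, 5): 0.4251, (9, 6): 0.3870,
    (10, 2): 0.7175, (10, 3): 0.5358, (10, 4): 0.4469, (10, 5): 0.3934, (10, 6): 0.3572,
    (11, 2): 0.6837, (11, 3): 0.5036, (11, 4): 0.4175, (11, 5): 0.3663, (11, 6): 0.3318,
    (12, 2): 0.6528, (12, 3): 0.4751, (12, 4): 0.3919, (12, 5): 0.3428, (12, 6): 0.3099,
    (13, 2): 0.6245, (13, 3): 0.4498, (13, 4): 0.3695, (13, 5): 0.3223, (13, 6): 0.2909,
    (14, 2): 0.5985, (14, 3): 0.4272, (14, 4): 0.3495, (14, 5): 0.3042, (14, 6): 0.2741,
    (15, 2): 0.5747, (15, 3): 0.4069, (15, 4): 0.3318, (15, 5): 0.2882, (15, 6): 0.2593,
    (16, 2): 0.5527, (16, 3): 0.3885, (16, 4): 0.3158, (16, 5): 0.2738, (16, 6): 0.2461,
    (17, 2): 0.5324, (17, 3): 0.3718, (17, 4): 0.3014, (17, 5): 0.2609, (17, 6): 0.2342,
    (18, 2): 0.5136, (18, 3): 0.3566, (18, 4): 0.2883, (18, 5): 0.2492, (18, 6): 0.2234,
    (19, 2): 0.4961, (19, 3): 0.3426, (19, 4): 0.2763, (19, 5): 0.2385, (19, 6): 0.2137,
    (20, 2): 0.4799, (20, 3): 0.3297, (20, 4): 0.2654, (20, 5): 0.2288, (20, 6): 0.2048,
    (21, 2): 0.4647, (21, 3): 0.3178, (21, 4): 0.2553, (21, 5): 0.2199, (21, 6): 0.1966,
    (22, 2): 0.4505, (22, 3): 0.3068, (22, 4): 0.2461, (22, 5): 0.2116, (22, 6): 0.1891,
    (23, 2): 0.4372, (23, 3): 0.2966, (23, 4): 0.2375, (23, 5): 0.2040, (23, 6): 0.1822,
    (24, 2): 0.4247, (24, 3): 0.2871, (24, 4): 0.2295, (24, 5): 0.1970, (24, 6): 0.1758,
    (25, 2): 0.4130, (25, 3): 0.2782, (25, 4): 0.2220, (25, 5): 0.1904, (25, 6): 0.1699,
    (26, 2): 0.4019, (26, 3): 0.2699, (26, 4): 0.2151, (26, 5): 0.1843, (26, 6): 0.1643,
    (27, 2): 0.3914, (27, 3): 0.2621, (27, 4): 0.2086, (27, 5): 0.1786, (27, 6): 0.1591,
    (28, 2): 0.3815, (28, 3): 0.2547, (28, 4): 0.2025, (28, 5): 0.1733, (28, 6): 0.1543,
    (29, 2): 0.3721, (29, 3): 0.2478, (29, 4): 0.1968, (29, 5): 0.1682, (29, 6): 0.1498,
    (30, 2): 0.3632, (30, 3): 0.2412, (30, 4): 0.1914, (30, 5): 0.1635, (30, 6): 0.1455,
}

# Grubbs G (single outlying laboratory mean), two-sided 1% level, keyed by p
GRUBBS_1PCT = {
    3: 1.1547, 4: 1.4963, 5: 1.7637, 6: 1.9728, 7: 2.1391, 8: 2.2744, 9: 2.3868, 10: 2.4821,
    11: 2.5641, 12: 2.6357, 13: 2.6990, 14: 2.7554, 15: 2.8061, 16: 2.8521, 17: 2.8940, 18: 2.9325,
    19: 2.9680, 20: 3.0008, 21: 3.0314, 22: 3.0599, 23: 3.0866, 24: 3.1117, 25: 3.1353, 26: 3.1577,
    27: 3.1788, 28: 3.1989, 29: 3.2179, 30: 3.2361, 31: 3.2534, 32: 3.2700, 33: 3.2858, 34: 3.3010,
    35: 3.3156, 36: 3.3296, 37: 3.3431, 38: 3.3561, 39: 3.3686, 40: 3.3807,
}


def cochran_critical_value(p: int, n: int) -> float:
    try:
        return COCHRAN_1PCT[(p, n)]
    except KeyError:
        raise ValueError(
            f"no 1% Cochran critical value tabulated for p={p}, n={n} "
            f"(table covers p=2..30, n=2..6)"
        ) from None


def grubbs_critical_value(p: int) -> float:
    try:
        return GRUBBS_1PCT[p]
    except KeyError:
        raise ValueError(
            f"no 1% Grubbs critical value tabulated for p={p} (table covers p=3..40)"
        ) from None
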