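"""Published per-group sample sizes for the two-sided two-sample t-test
(alpha = 0.05, beta = 0.2) over the standard k x CV planning grid.

Rows follow CV_GRID, columns follow K_GRID (k = 1.10 ... 2.00 step 0.05).
"""

K_GRID = tuple(round(1.10 + 0.05 * i, 2) for i in range(19))
CV_GRID = (0.03, 0.05) + tuple(round(0.10 + 0.05 * i, 2) for i in range(11)) + (0.70, 0.80, 0.90)

GOLDEN = (
    (3, 3, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2),
    (6, 4, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2),
    (17, 9, 6, 4, 4, 3, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2, 2),
    (37, 17, 10, 7, 6, 5, 4, 4, 3, 3, 3, 3, 3, 3, 3, 2, 2, 2, 2),
    (64, 29, 17, 12, 9, 7, 6, 5, 4, 4, 4, 3, 3, 3, 3, 3, 3, 3, 3),
    (100, 45, 26, 17, 12, 10, 8, 6, 6, 5, 4, 4, 4, 4, 3, 3, 3, 3, 3),
    (143, 64, 37, 24, 17, 13, 10, 9, 7, 6, 6, 5, 5, 4, 4, 4, 4, 3, 3),
    (194, 87, 50, 32, 23, 17, 14, 11, 9, 8, 7, 6, 6, 5, 5, 4, 4, 4, 4),
    (253, 113, 64, 42, 29, 22, 17, 14, 12, 10, 9, 8, 7, 6, 6, 5, 5, 5, 4),
    (319, 143, 81, 52, 37, 27, 21, 17, 14, 12, 10, 9, 8, 7, 7, 6, 6, 5, 5),
    (394, 176, 100, 64, 45, 34, 26, 21, 17, 15, 12, 11, 10, 9, 8, 7, 6, 6, 6),
    (476, 213, 120, 77, 54, 40, 31, 25, 21, 17, 15, 13, 11, 10, 9, 8, 7, 7, 6),
    (567, 253, 143, 92, 64, 48, 37, 29, 24, 20, 17, 15, 13, 12, 10, 9, 9, 8, 7),
    (771, 343, 194, 125, 87, 64, 50, 39, 32, 27, 23, 20, 17, 15, 14, 12, 11, 10, 9),
    (1006, 448, 253, 162, 113, 83, 64, 51, 42, 35, 29, 25, 22, 19, 17, 15, 14, 13, 12),
    (1273, 567, 319, 205, 143, 105, 81, 64, 52, 44, 37, 32, 27, 24, 21, 19, 17, 16, 14),
)
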