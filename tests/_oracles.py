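"""Independent brute-force oracles shared by unit and acceptance tests."""

import numpy as np


def anova_icc_2_1_oracle(x, y):
    """ICC(2,1) from an explicit two-way ANOVA decomposition, loop-based.

    Independent of the package implementation: sums of squares are
    accumulated cell by cell over the n x 2 (target x rater) table.
    """
    table = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = table.shape
    grand = table.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += (table[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += (table[:, j].mean() - grand) ** 2
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            pred = table[i].mean() + table[:, j].mean() - grand
            ss_err += (table[i, j] - pred) ** 2
    msr = k * ss_rows / (n - 1)
    msc = n * ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def wscv_hand_oracle(subject_vectors):
    """Root-mean-square of per-subject CVs, percent, by explicit loops."""
    cv2 = []
    for v in subject_vectors:
        v = np.asarray(v, float)
        m = v.mean()
        s = np.sqrt(((v - m) ** 2).sum() / (v.size - 1))
        cv2.append((s / m) ** 2)
    return 100.0 * np.sqrt(sum(cv2) / len(cv2))
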