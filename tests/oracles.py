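"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written with naive loops and textbook formulas, on
purpose: these functions certify the vectorised implementations and must
not share code paths with them.
"""

import math


def oneway_f_bruteforce(groups):
    """Textbook one-way ANOVA F from raw values, pure-Python loops."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ss_between += len(g) * (m - grand) ** 2
        for x in g:
            ss_within += (x - m) ** 2
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


def repeated_f_bruteforce(matrix):
    """Textbook one-way repeated-measures F, pure-Python loops."""
    n = len(matrix)
    t = len(matrix[0])
    grand = sum(sum(row) for row in matrix) / (n * t)
    col_means = [sum(matrix[i][j] for i in range(n)) / n for j in range(t)]
    row_means = [sum(row) / t for row in matrix]
    ss_total = sum((matrix[i][j] - grand) ** 2
                   for i in range(n) for j in range(t))
    ss_time = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_subject = t * sum((rm - grand) ** 2 for rm in row_means)
    ss_error = ss_total - ss_time - ss_subject
    ms_time = ss_time / (t - 1)
    ms_error = ss_error / ((t - 1) * (n - 1))
    return ms_time / ms_error, (t - 1), (t - 1) * (n - 1)


def oneway_f_from_summary(ns, means, sds):
    """Closed-form one-way ANOVA F from per-group summary statistics."""
    n_total = sum(ns)
    grand = sum(n * m for n, m in zip(ns, means)) / n_total
    ss_between = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    ss_within = sum((n - 1) * s ** 2 for n, s in zip(ns, sds))
    df_b = len(ns) - 1
    df_w = n_total - len(ns)
    return (ss_between / df_b) / (ss_within / df_w)


def two_sided_t_pvalue_betainc(t_stat, df):
    """Two-sided t p-value through the regularised incomplete beta function.

    Uses the closed form P(|T| > t) = I_{df/(df+t^2)}(df/2, 1/2) evaluated
    by scipy.special.betainc — a different route than the t CDF used in the
    implementation.
    """
    from scipy.special import betainc

    return float(betainc(df / 2.0, 0.5, df / (df + t_stat * t_stat)))


def mean_two_pass(values):
    """Two-pass compensated mean."""
    m = sum(values) / len(values)
    correction = sum(v - m for v in values) / len(values)
    return m + correction


def sd_two_pass(values):
    m = mean_two_pass(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def biexp_signal_scalar(f, d, d_star, b):
    """Scalar math.exp evaluation of the biexponential decay."""
    return (1.0 - f) * math.exp(-b * d) + f * math.exp(-b * (d + d_star))
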