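"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops over rows/pairs, with no
code shared with the package, so that agreement is a meaningful check.
"""

import numpy as np
from scipy.stats import pearsonr, spearmanr


# --- transforms ------------------------------------------------------------

def prop_rows(x):
    out = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        out[i] = x[i] / x[i].sum()
    return out


def hellinger_rows(x):
    return np.sqrt(prop_rows(x))


def chi_square_cells(x):
    grand = x.sum()
    out = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            col = x[:, j].sum()
            if col > 0:
                out[i, j] = x[i, j] * np.sqrt(grand) / (x[i].sum() * np.sqrt(col))
    return out


def clr_rows(x, pc):
    out = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        logs = np.log(x[i] + pc)
        out[i] = logs - logs.mean()
    return out


def rclr_rows(x):
    out = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        nz = np.flatnonzero(x[i])
        gmean = np.exp(np.mean([np.log(x[i, j]) for j in nz]))
        for j in nz:
            out[i, j] = np.log(x[i, j] / gmean)
    return out


def gmpr_factors(x):
    n = x.shape[0]
    s = np.zeros(n)
    for i in range(n):
        logs = []
        for j in range(n):
            if i == j:
                continue
            ratios = [x[i, k] / x[j, k] for k in range(x.shape[1])
                      if x[i, k] > 0 and x[j, k] > 0]
            if ratios:
                logs.append(np.log(np.median(ratios)))
        s[i] = np.exp(np.mean(logs))
    return s


def kmer_rows(x, sequences, k):
    from itertools import product
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    freq = np.zeros((len(sequences), len(kmers)))
    for j, seq in enumerate(sequences):
        for start in range(len(seq) - k + 1):
            freq[j, kmers.index(seq[start:start + k])] += 1
        freq[j] /= freq[j].sum()
    out = np.zeros((x.shape[0], len(kmers)))
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            out[i] += x[i, j] * freq[j]
        out[i] /= out[i].sum()
    return out


# --- distances -------------------------------------------------------------

def pair_matrix(x, fn):
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = fn(x[i], x[j])
    return d


def bray(a, b):
    return sum(abs(a[k] - b[k]) for k in range(len(a))) / (a.sum() + b.sum())


def canberra(a, b):
    terms, nz = 0.0, 0
    for k in range(len(a)):
        if a[k] > 0 or b[k] > 0:
            terms += abs(a[k] - b[k]) / (a[k] + b[k])
            nz += 1
    return terms / nz


def kulczynski(a, b):
    mins = sum(min(a[k], b[k]) for k in range(len(a)))
    return 1 - 0.5 * (mins / a.sum() + mins / b.sum())


def horn(a, b):
    la = sum(v * v for v in a) / a.sum() ** 2
    lb = sum(v * v for v in b) / b.sum() ** 2
    return 1 - 2 * sum(a[k] * b[k] for k in range(len(a))) / ((la + lb) * a.sum() * b.sum())


def alt_gower(a, b):
    terms = [abs(a[k] - b[k]) for k in range(len(a)) if a[k] > 0 or b[k] > 0]
    return sum(terms) / len(terms)


def gower_matrix(x):
    n, p = x.shape
    std = np.zeros_like(x, dtype=float)
    for j in range(p):
        lo, hi = x[:, j].min(), x[:, j].max()
        if hi > lo:
            std[:, j] = (x[:, j] - lo) / (hi - lo)
    return pair_matrix(std, lambda a, b: np.mean([abs(a[k] - b[k]) for k in range(p)]))


def pearson_dist(a, b):
    return 1 - pearsonr(a, b)[0]


def spearman_dist(a, b):
    return 1 - spearmanr(a, b)[0]


def tina_identity(a, b):
    """Interaction-adjusted similarity with identity association reduces to
    the cosine of the relative-abundance vectors."""
    wa, wb = a / a.sum(), b / b.sum()
    return 1 - float(wa @ wb / (np.linalg.norm(wa) * np.linalg.norm(wb)))


def weighted_unifrac_two_tips(pa, pb, la, lb):
    """Weighted UniFrac on a two-tip star tree with branch lengths la, lb
    and per-sample tip masses pa, pb (each sums to 1)."""
    num = la * abs(pa[0] - pb[0]) + lb * abs(pa[1] - pb[1])
    den = la * (pa[0] + pb[0]) + lb * (pa[1] + pb[1])
    return num / den


# --- PERMANOVA -------------------------------------------------------------

def permanova_f_oracle(d, labels):
    """Pseudo-F via explicit sums of squared distances (one-way design)."""
    n = d.shape[0]
    labels = np.asarray(labels)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    a = len(np.unique(labels))
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova_f_centered_oracle(d, labels):
    """Pseudo-F via explicit Gower centering and projection matrices."""
    n = d.shape[0]
    labels = np.asarray(labels)
    a2 = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a2 @ centering
    groups = np.unique(labels)
    x = np.array([[1.0 if labels[i] == grp else 0.0 for grp in groups]
                  for i in range(n)])
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    df_model = len(groups) - 1
    df_resid = n - len(groups)
    ss_model = np.trace(h @ g @ h)
    ss_resid = np.trace((np.eye(n) - h) @ g @ (np.eye(n) - h))
    return (ss_model / df_model) / (ss_resid / df_resid)
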