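"""Count transformations for compositional community matrices.

All thirteen methods are exposed through :func:`transform` with a single
options object. Methods fall into three families:

* simple rescalings — proportions, rarefaction, Hellinger, chi-square;
* log-ratio transforms — clr (pseudocount) and robust clr (zeros kept);
* model-based library-size normalizations — CSS (cumulative-sum scaling),
  VST (closed-form negative-binomial variance stabilization with a fitted
  a/mu + b dispersion trend), TMM and TMMwsp (trimmed mean of M-values,
  applied as effective-library-size log-CPM), wrench (group-aware
  compositional factors from shrunken proportion ratios) and GMPR
  (geometric mean of pairwise count-ratio medians);

plus the sequence-based k-mer decomposition, which replaces taxon features
by k-mer frequency profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, TransformedMatrix

TRANSFORM_METHODS = ("prop", "rarefy", "hellinger", "chi_square", "css", "clr",
                     "rclr", "vst", "tmm", "tmmwsp", "wrench", "gmpr", "kmer")


@dataclass
class TransformOptions:
    method: str = "prop"
    rarefy_depth: int | str = "min"
    clr_pseudocount: float = 1.0
    kmer_k: int = 5
    wrench_groups: pd.Series | None = None
    seed: int = 0
    sequences: dict[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in TRANSFORM_METHODS:
            raise ConfigurationError(f"unknown transform {self.method!r}")
        if self.clr_pseudocount < 0:
            raise ConfigurationError("clr_pseudocount must be nonnegative")
        if self.kmer_k < 1:
            raise ConfigurationError("kmer_k must be positive")


def _as_float(counts: pd.DataFrame) -> np.ndarray:
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    return x


def _prop(x: np.ndarray) -> np.ndarray:
    return x / x.sum(axis=1, keepdims=True)


def _rarefy(counts: pd.DataFrame, depth: int | str, seed: int) -> np.ndarray:
    x = counts.to_numpy(dtype=np.int64)
    totals = x.sum(axis=1)
    if depth == "min":
        depth = int(totals.min())
    depth = int(depth)
    short = np.flatnonzero(totals < depth)
    if short.size:
        raise ValueError(
            f"rarefaction depth {depth} exceeds total of sample(s) "
            f"{[counts.index[i] for i in short[:5]]}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = rng.multivariate_hypergeometric(x[i], depth)
    return out.astype(float)


def _chi_square(x: np.ndarray) -> np.ndarray:
    # x_ij * sqrt(grand total) / (row_i * sqrt(col_j)); all-zero columns -> 0
    grand = x.sum()
    rows = x.sum(axis=1, keepdims=True)
    cols = x.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x * np.sqrt(grand) / (rows * np.sqrt(cols))
    return np.where(cols > 0, out, 0.0)


def _clr(x: np.ndarray, pseudocount: float) -> np.ndarray:
    if pseudocount == 0 and (x == 0).any():
        raise ValueError("clr with zeros requires a positive pseudocount")
    logx = np.log(x + pseudocount)
    return logx - logx.mean(axis=1, keepdims=True)


def _rclr(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        nz = x[i] > 0
        logs = np.log(x[i, nz])
        out[i, nz] = logs - logs.mean()
    return out


# --- CSS -------------------------------------------------------------------

def css_quantile(x: np.ndarray, probs: np.ndarray | None = None,
                 instability: float = 0.10) -> float:
    """Data-driven CSS quantile.

    Scans candidate quantiles of each sample's nonzero count distribution,
    compares them to the across-sample median reference curve, and picks
    the smallest quantile at which the median absolute deviation from the
    reference starts growing faster than ``instability`` (relative step
    increase). Falls back to 0.50 when no instability point is found.
    """
    if probs is None:
        probs = np.arange(0.25, 0.96, 0.01)
    qmat = []
    for row in x:
        nz = row[row > 0]
        if nz.size == 0:
            continue
        qmat.append(np.quantile(nz, probs))
    if len(qmat) < 2:
        return 0.50
    qmat = np.asarray(qmat)
    ref = np.median(qmat, axis=0)
    dev = np.median(np.abs(qmat - ref[None, :]), axis=0)
    for k in range(len(probs) - 1):
        if probs[k] < 0.50 or dev[k] <= 0:
            continue
        if (dev[k + 1] - dev[k]) / dev[k] > instability:
            return float(probs[k])
    return 0.50


def css_factors(x: np.ndarray, quantile: float | None = None) -> np.ndarray:
    """Per-sample cumulative-sum scaling factors (sum of counts up to the
    chosen quantile of the sample's nonzero counts)."""
    if quantile is None:
        quantile = css_quantile(x)
    s = np.empty(x.shape[0])
    for i, row in enumerate(x):
        nz = row[row > 0]
        if nz.size == 0:
            raise ValueError("CSS undefined for an all-zero sample")
        cutoff = np.quantile(nz, quantile)
        s[i] = row[(row > 0) & (row <= cutoff)].sum()
        if s[i] == 0:
            s[i] = nz.min()
    return s


def _css(x: np.ndarray) -> np.ndarray:
    s = css_factors(x)
    return x / s[:, None] * np.median(s)


# --- VST -------------------------------------------------------------------

def median_of_ratios_factors(x: np.ndarray) -> np.ndarray:
    """DESeq-style size factors using the positive-count geometric mean as
    the per-taxon reference (robust to zeros)."""
    with np.errstate(divide="ignore"):
        logx = np.where(x > 0, np.log(x), np.nan)
    ref = np.exp(np.nanmean(logx, axis=0))
    s = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        ok = (x[i] > 0) & np.isfinite(ref) & (ref > 0)
        if not ok.any():
            raise ValueError("cannot estimate a size factor for an all-zero sample")
        s[i] = np.median(x[i, ok] / ref[ok])
    s /= np.exp(np.mean(np.log(s)))
    return s


def _vst(x: np.ndarray) -> np.ndarray:
    s = median_of_ratios_factors(x)
    q = x / s[:, None]
    mu = q.mean(axis=0)
    var = q.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros_like(mu)
    ok = mu > 0.5
    # method-of-moments dispersions, then a parametric a/mu + b trend
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mu) / mu**2
    fit_ok = ok & np.isfinite(disp) & (disp > 0)
    if fit_ok.sum() >= 2:
        design = np.column_stack([1.0 / mu[fit_ok], np.ones(int(fit_ok.sum()))])
        coef, *_ = np.linalg.lstsq(design, disp[fit_ok], rcond=None)
        a, b = float(coef[0]), float(coef[1])
    else:
        a, b = 0.0, 0.1
    a = max(a, 0.0)
    b = max(b, 1e-4)
    # closed-form VST for NB with dispersion trend a/mu + b
    return np.log2((1 + a + 2 * b * q + 2 * np.sqrt(b * q * (1 + a + b * q)))
                   / (4 * b))


# --- TMM / TMMwsp ----------------------------------------------------------

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     lib_obs: float, lib_ref: float,
                     logratio_trim: float = 0.30,
                     sum_trim: float = 0.05) -> float:
    """Trimmed mean of M-values factor of one sample against the reference."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = int(np.floor(n * logratio_trim)) + 1
    hi_l = n + 1 - lo_l
    lo_s = int(np.floor(n * sum_trim)) + 1
    hi_s = n + 1 - lo_s
    from scipy.stats import rankdata

    rank_l = rankdata(log_r)  # average ranks on ties, as in the reference
    rank_s = rankdata(abs_e)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f) if np.isfinite(f) else 1.0


def _tmmwsp_pair_factor(obs: np.ndarray, ref: np.ndarray) -> float:
    """TMM with singleton pairing: taxa positive in only one of the two
    samples are paired off (largest against largest) instead of discarded."""
    obs = obs.astype(float).copy()
    ref = ref.astype(float).copy()
    lib_obs, lib_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    obs_only = (obs > 0) & (ref == 0)
    ref_only = (ref > 0) & (obs == 0)
    n_pair = int(min(obs_only.sum(), ref_only.sum()))
    x = obs[both]
    r = ref[both]
    if n_pair > 0:
        x = np.concatenate([x, np.sort(obs[obs_only])[::-1][:n_pair]])
        r = np.concatenate([r, np.sort(ref[ref_only])[::-1][:n_pair]])
    if x.size == 0:
        return 1.0
    obs_p = x / lib_obs
    ref_p = r / lib_ref
    m = np.log2(obs_p / ref_p)
    if x.size == 1:
        return float(2.0 ** m[0])
    a = 0.5 * np.log2(obs_p * ref_p)
    m_shrunk = np.log2(((x + 0.5) / (lib_obs + 0.5)) / ((r + 0.5) / (lib_ref + 0.5)))
    n = m.size
    o_m = np.lexsort((m_shrunk, m))
    o_a = np.argsort(a, kind="stable")
    lo_m = int(n * 0.30)
    lo_a = int(n * 0.05)
    keep = np.zeros(n, dtype=bool)
    keep_a = np.zeros(n, dtype=bool)
    keep[o_m[lo_m: n - lo_m]] = True
    keep_a[o_a[lo_a: n - lo_a]] = True
    keep &= keep_a
    if not keep.any():
        return 1.0
    op, rp = obs_p[keep], ref_p[keep]
    v = (1.0 - op) / op / lib_obs + (1.0 - rp) / rp / lib_ref
    w = (1.0 + 1e-6) / (v + 1e-6)
    return float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))


def tmm_norm_factors(x: np.ndarray, singleton_pairing: bool = False) -> np.ndarray:
    """edgeR-style TMM normalization factors, geometric-mean centred."""
    libs = x.sum(axis=1)
    x = x[:, x.sum(axis=0) > 0]  # drop taxa absent everywhere
    if singleton_pairing:
        ref_idx = int(np.argmax(np.sqrt(x).sum(axis=1)))
    else:
        q75 = np.array([np.quantile(row / lib, 0.75) for row, lib in zip(x, libs)])
        if np.median(q75) < 1e-20:
            ref_idx = int(np.argmax(np.sqrt(x).sum(axis=1)))
        else:
            ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = x[ref_idx]
    f = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        if singleton_pairing:
            f[i] = _tmmwsp_pair_factor(x[i], ref)
        else:
            f[i] = _tmm_pair_factor(x[i], ref, libs[i], libs[ref_idx])
    f /= np.exp(np.mean(np.log(f)))
    return f


def _tmm(x: np.ndarray, singleton_pairing: bool) -> np.ndarray:
    f = tmm_norm_factors(x, singleton_pairing=singleton_pairing)
    eff_lib = x.sum(axis=1) * f
    # log2 counts-per-million against the effective library size
    return np.log2((x + 0.5) / (eff_lib[:, None] + 1.0) * 1e6)


# --- wrench / GMPR ---------------------------------------------------------

def wrench_factors(x: np.ndarray, groups: np.ndarray | None = None) -> np.ndarray:
    """Compositional scale factors from shrunken proportion ratios.

    For each sample, log ratios of its taxon proportions to the average
    proportion profile are averaged over detected taxa, with the sample
    mean shrunk toward its group mean by an inverse-variance weight, and
    corrected by the sample's detection fraction relative to its group
    (the hurdle part: heavily zero-inflated samples get smaller factors).
    """
    n = x.shape[0]
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)
    props = x / x.sum(axis=1, keepdims=True)
    ref = props.mean(axis=0)
    log_s = np.empty(n)
    detect = (x > 0).mean(axis=1)
    sample_means = np.empty(n)
    sample_vars = np.empty(n)
    sample_m = np.empty(n)
    for i in range(n):
        nz = (x[i] > 0) & (ref > 0)
        if not nz.any():
            raise ValueError("wrench undefined for an all-zero sample")
        lr = np.log(props[i, nz] / ref[nz])
        sample_means[i] = lr.mean()
        sample_vars[i] = lr.var(ddof=1) if nz.sum() > 1 else 0.0
        sample_m[i] = nz.sum()
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        mu_g = sample_means[members].mean()
        tau2 = sample_means[members].var(ddof=1) if members.size > 1 else 0.0
        det_g = detect[members].mean()
        for i in members:
            sigma2 = sample_vars[i] / max(sample_m[i], 1.0)
            w = tau2 / (tau2 + sigma2) if (tau2 + sigma2) > 0 else 1.0
            shrunk = w * sample_means[i] + (1 - w) * mu_g
            hurdle = detect[i] / det_g if det_g > 0 else 1.0
            log_s[i] = shrunk + np.log(hurdle)
    s = np.exp(log_s)
    s /= np.exp(np.mean(np.log(s)))
    return s


def _wrench(x: np.ndarray, groups: pd.Series | None) -> np.ndarray:
    g = None if groups is None else np.asarray(groups)
    s = wrench_factors(x, g)
    return x / (x.sum(axis=1) * s)[:, None] * x.sum(axis=1).mean()


def gmpr_size_factors(x: np.ndarray) -> np.ndarray:
    """Geometric mean of median pairwise count ratios over shared taxa."""
    n = x.shape[0]
    s = np.empty(n)
    for i in range(n):
        logs = []
        for j in range(n):
            if i == j:
                continue
            shared = (x[i] > 0) & (x[j] > 0)
            if not shared.any():
                continue
            logs.append(np.log(np.median(x[i, shared] / x[j, shared])))
        if not logs:
            raise ValueError(f"sample {i} shares no taxa with any other sample")
        s[i] = np.exp(np.mean(logs))
    return s


def _gmpr(x: np.ndarray) -> np.ndarray:
    s = gmpr_size_factors(x)
    return x / s[:, None]


# --- k-mer decomposition ---------------------------------------------------

def kmer_profile(sequence: str, k: int) -> np.ndarray:
    """Frequency vector over the 4**k k-mers of one sequence."""
    index = {"".join(p): i for i, p in enumerate(product("ACGT", repeat=k))}
    vec = np.zeros(len(index))
    for i in range(len(sequence) - k + 1):
        vec[index[sequence[i:i + k]]] += 1
    total = vec.sum()
    if total == 0:
        raise ValueError("sequence shorter than k")
    return vec / total


def _kmer(counts: pd.DataFrame, sequences: dict[str, str], k: int,
          ) -> tuple[np.ndarray, list[str]]:
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    index = {km: i for i, km in enumerate(kmers)}
    freq = np.zeros((counts.shape[1], len(kmers)))
    for j, tid in enumerate(counts.columns):
        seq = sequences[tid]
        for i in range(len(seq) - k + 1):
            freq[j, index[seq[i:i + k]]] += 1
        if freq[j].sum() == 0:
            raise ValueError(f"sequence of taxon {tid!r} shorter than k={k}")
        freq[j] /= freq[j].sum()
    profile = counts.to_numpy(dtype=float) @ freq
    profile /= profile.sum(axis=1, keepdims=True)
    return profile, kmers


# --- dispatch --------------------------------------------------------------

def transform(counts: pd.DataFrame, options: TransformOptions) -> TransformedMatrix:
    """Apply one of the thirteen count transformations.

    Returns a real-valued samples x features matrix; features are the
    input taxa except for the k-mer method, whose features are k-mers.
    """
    method = options.method
    x = _as_float(counts)
    feature_ids = list(counts.columns)
    taxon_features = True

    if method == "prop":
        out = _prop(x)
    elif method == "rarefy":
        out = _rarefy(counts, options.rarefy_depth, options.seed)
    elif method == "hellinger":
        out = np.sqrt(_prop(x))
    elif method == "chi_square":
        out = _chi_square(x)
    elif method == "css":
        out = _css(x)
    elif method == "clr":
        out = _clr(x, options.clr_pseudocount)
    elif method == "rclr":
        out = _rclr(x)
    elif method == "vst":
        out = _vst(x)
    elif method in ("tmm", "tmmwsp"):
        out = _tmm(x, singleton_pairing=(method == "tmmwsp"))
    elif method == "wrench":
        out = _wrench(x, options.wrench_groups)
    elif method == "gmpr":
        out = _gmpr(x)
    elif method == "kmer":
        if not options.sequences:
            raise ValueError("kmer transform requires per-taxon sequences")
        out, feature_ids = _kmer(counts, options.sequences, options.kmer_k)
        taxon_features = False
    else:  # pragma: no cover - guarded in TransformOptions
        raise ConfigurationError(method)

    frame = pd.DataFrame(out, index=counts.index, columns=feature_ids)
    return TransformedMatrix(data=frame, method=method,
                             taxon_features=taxon_features)
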