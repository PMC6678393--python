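"""TMM normalization and negative-binomial exact-test differential abundance.

The model is NB with Var = mu + phi * mu^2 (phi = 0 is Poisson). The workflow
is the classical count-based small-sample one:

1. ``tmm_factors`` — one scaling factor per sample from the weighted trimmed
   mean of M-values against a reference sample, rescaled to geometric mean 1.
2. ``estimate_common_dispersion`` — a single cohort-level phi maximizing the
   conditional NB likelihood on library-size-equalized pseudo-counts.
3. ``nb_exact_test`` — per feature, the two-sided exact p-value from the
   conditional distribution of one group's (pseudo-)total given the overall
   total; two-sidedness by the minimum-likelihood rule (sum the probabilities
   of all splits no more likely than the observed one).
4. ``call_de`` — the selection rule p < 0.05 and max(FC, 1/FC) > 1.5.
5. ``ev_partition`` — the same machinery with plasma fraction (EV vs EVD) as
   the grouping variable, yielding EV-enriched and EV-underrepresented sets.
6. ``motif_scan`` — GGAG / GGCU EV-sorting motifs at the 3' end of mature
   sequences, as terminal suffix or within a short 3' window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .io import ConfigError, CountMatrix, DataError

#: proportional prior (per effective library) used only when reporting a
#: fold-change whose group mean is zero; never enters the test itself
FC_PRIOR_COUNT = 0.125


def _as_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    kept = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not kept.any() or not np.isfinite(var[kept]).all():
        return 1.0
    f = np.sum(log_r[kept] / var[kept]) / np.sum(1.0 / var[kept])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts, ref_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    M-values (between-sample log2 fold-changes) and A-values (average log2
    abundances) are computed per feature against a reference sample (by
    default the one whose 75th-percentile count share is closest to the
    cohort mean); the most extreme ``trim_m`` of each M tail and ``trim_a``
    of each A tail are discarded and the remaining M-values averaged with
    inverse asymptotic-variance weights. Factors are rescaled so their
    geometric mean is exactly 1.
    """
    df = _as_frame(counts)
    if df.shape[1] < 2:
        raise ConfigError("TMM needs at least two samples")
    lib = df.sum(axis=0).astype(float)
    zero = lib[lib == 0]
    if len(zero):
        raise DataError(f"sample(s) with zero total counts: {list(zero.index)}")
    mat = df.to_numpy(dtype=float)
    if ref_sample is None:
        f75 = np.array([np.quantile(mat[:, j] / lib.iloc[j], 0.75) for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = int(df.columns.get_loc(ref_sample))
    ref = mat[:, ref_idx]
    n_ref = lib.iloc[ref_idx]
    factors = np.array(
        [_tmm_pair(mat[:, j], ref, lib.iloc[j], n_ref, trim_m, trim_a) for j in range(mat.shape[1])]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


def effective_lib_sizes(counts, factors: pd.Series) -> pd.Series:
    df = _as_frame(counts)
    return df.sum(axis=0).astype(float) * factors.reindex(df.columns)


def cpm(counts, factors: pd.Series) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    df = _as_frame(counts)
    return df / effective_lib_sizes(df, factors) * 1e6


# ---------------------------------------------------------------------------
# library-size equalization (quantile-to-quantile NB pseudo-counts)
# ---------------------------------------------------------------------------

def _q2q_nbinom(x: np.ndarray, in_mean: np.ndarray, out_mean: np.ndarray, phi: float) -> np.ndarray:
    """Map counts between NB distributions quantile-for-quantile.

    Averages a normal and a gamma approximation of the NB percentile of each
    observation under its input mean, re-expressed at the output mean.
    """
    eps = 1e-4
    in_mean = np.where(in_mean < eps, in_mean + 0.25, in_mean)
    out_mean = np.where(out_mean < eps, out_mean + 0.25, out_mean)
    r_i = 1.0 + phi * in_mean
    r_o = 1.0 + phi * out_mean
    sd_i = np.sqrt(in_mean * r_i)
    sd_o = np.sqrt(out_mean * r_o)

    out = np.empty_like(x, dtype=float)
    upper = x >= in_mean
    for mask, tail in ((upper, "sf"), (~upper, "cdf")):
        if not mask.any():
            continue
        xm, imu, omu = x[mask], in_mean[mask], out_mean[mask]
        rim, rom = r_i[mask], r_o[mask]
        sim, som = sd_i[mask], sd_o[mask]
        if tail == "sf":
            p_n = np.clip(stats.norm.sf(xm, imu, sim), 1e-300, 1.0)
            p_g = np.clip(stats.gamma.sf(xm, a=imu / rim, scale=rim), 1e-300, 1.0)
            q_n = stats.norm.isf(p_n, omu, som)
            q_g = stats.gamma.isf(p_g, a=omu / rom, scale=rom)
        else:
            p_n = np.clip(stats.norm.cdf(xm, imu, sim), 1e-300, 1.0)
            p_g = np.clip(stats.gamma.cdf(xm, a=imu / rim, scale=rim), 1e-300, 1.0)
            q_n = stats.norm.ppf(p_n, omu, som)
            q_g = stats.gamma.ppf(p_g, a=omu / rom, scale=rom)
        out[mask] = (q_n + q_g) / 2.0
    return out


def _one_group_log_mean(y: np.ndarray, libs: np.ndarray, phi: float, iters: int = 50) -> np.ndarray:
    """Per-feature NB MLE of abundance per unit library (Fisher scoring)."""
    total = y.sum(axis=1)
    lam = np.where(total > 0, total / libs.sum(), 0.0)
    pos = total > 0
    beta = np.log(np.where(pos, lam, 1.0))
    for _ in range(iters):
        mu = np.exp(beta)[:, None] * libs[None, :]
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(pos & (info > 0), score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    lam = np.where(pos, np.exp(beta), 0.0)
    return lam


def equalize_lib_sizes(counts, groups: pd.Series, eff_lib: pd.Series, phi: float) -> tuple[pd.DataFrame, float]:
    """Pseudo-counts re-expressed at a common (geometric-mean) library size."""
    df = _as_frame(counts)
    y = df.to_numpy(dtype=float)
    libs = eff_lib.reindex(df.columns).to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(libs))))
    in_mean = np.empty_like(y)
    out_mean = np.empty_like(y)
    g = groups.reindex(df.columns)
    for level in g.unique():
        cols = np.where((g == level).to_numpy())[0]
        lam = _one_group_log_mean(y[:, cols], libs[cols], phi)
        in_mean[:, cols] = lam[:, None] * libs[cols][None, :]
        out_mean[:, cols] = lam[:, None] * common
    pseudo = _q2q_nbinom(y, in_mean, out_mean, phi)
    pseudo = np.maximum(pseudo, 0.0)
    return pd.DataFrame(pseudo, index=df.index, columns=df.columns), common


# ---------------------------------------------------------------------------
# common dispersion (conditional maximum likelihood)
# ---------------------------------------------------------------------------

def _common_cond_loglik(phi: float, group_blocks: list[np.ndarray]) -> float:
    total = 0.0
    r = 1.0 / phi
    for block in group_blocks:  # features x samples, library sizes equalized
        n_feat, n = block.shape
        z = block.sum(axis=1)
        total += float(
            np.sum(gammaln(block + r))
            + n_feat * (gammaln(n * r) - n * gammaln(r))
            - np.sum(gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(counts, groups: pd.Series, factors: pd.Series,
                               n_iter: int = 2) -> float:
    """Cohort-level NB dispersion phi by conditional maximum likelihood.

    Alternates library-size equalization (which needs phi) with maximization
    of the conditional log-likelihood, starting from phi = 0.01. Estimates
    driven to the optimizer's lower bound are reported as exactly 0 (Poisson).
    """
    df = _as_frame(counts)
    g = groups.reindex(df.columns)
    sizes = g.value_counts()
    if (sizes < 2).any():
        raise DataError(f"every group needs >= 2 samples; got {sizes.to_dict()}")
    eff_lib = effective_lib_sizes(df, factors)
    phi = 0.01
    for _ in range(n_iter):
        pseudo, _ = equalize_lib_sizes(df, g, eff_lib, phi)
        blocks = [pseudo.loc[:, (g == level).to_numpy()].to_numpy() for level in g.unique()]

        def neg_ll(delta: float) -> float:
            return -_common_cond_loglik(delta / (1.0 - delta), blocks)

        res = optimize.minimize_scalar(neg_ll, bounds=(1e-6, 0.99), method="bounded",
                                       options={"xatol": 1e-8})
        delta = float(res.x)
        phi = delta / (1.0 - delta)
        if delta <= 2e-6:
            return 0.0
    return phi


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _exact_p(z1: int, z2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p for observed group totals (z1, z2).

    Conditions on z = z1 + z2; under phi = 0 the split is Binomial(z,
    n1/(n1+n2)), otherwise it follows the NB convolution ratio with sizes
    n1/phi and n2/phi. The p-value sums the probabilities of every split as or
    less likely than the observed one (minimum-likelihood rule), capped at 1.
    """
    z = z1 + z2
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if phi <= 0:
        logpmf = stats.binom.logpmf(k, z, n1 / (n1 + n2))
    else:
        r = 1.0 / phi
        logpmf = (
            gammaln(k + n1 * r) - gammaln(k + 1)
            + gammaln(z - k + n2 * r) - gammaln(z - k + 1)
        )
        logpmf = logpmf - logsumexp(logpmf)
    keep = logpmf <= logpmf[z1] + 1e-10
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]) - logsumexp(logpmf))))


def nb_exact_test(counts, groups: pd.Series, factors: pd.Series, dispersion: float,
                  numerator: str | None = None, denominator: str | None = None) -> pd.DataFrame:
    """Per-feature exact NB test of abundance between two groups.

    Group totals are formed on library-size-equalized pseudo-counts and
    rounded; the fold-change is the ratio of mean normalized abundances (CPM),
    ``numerator`` over ``denominator``, with a small proportional prior added
    to both means only when one of them is zero. Features that are all-zero
    get p = 1 and FC = 1 and are flagged.
    """
    df = _as_frame(counts)
    g = groups.reindex(df.columns)
    levels = list(pd.unique(g))
    if len(levels) != 2:
        raise DataError(f"exact test needs exactly two groups, got {levels}")
    if numerator is None or denominator is None:
        denominator, numerator = levels[0], levels[1]
    if {numerator, denominator} != set(levels):
        raise ConfigError(f"groups {levels} do not match {numerator!r}/{denominator!r}")

    eff_lib = effective_lib_sizes(df, factors)
    pseudo, _ = equalize_lib_sizes(df, g, eff_lib, dispersion)
    num_cols = (g == numerator).to_numpy()
    den_cols = (g == denominator).to_numpy()
    z_num = np.round(pseudo.loc[:, num_cols].sum(axis=1)).astype(np.int64)
    z_den = np.round(pseudo.loc[:, den_cols].sum(axis=1)).astype(np.int64)
    n_num, n_den = int(num_cols.sum()), int(den_cols.sum())

    cpm_mat = cpm(df, factors)
    mean_num = cpm_mat.loc[:, num_cols].mean(axis=1)
    mean_den = cpm_mat.loc[:, den_cols].mean(axis=1)
    prior_cpm = FC_PRIOR_COUNT / float(eff_lib.mean()) * 1e6
    needs_prior = (mean_num == 0) | (mean_den == 0)
    fc_num = mean_num + np.where(needs_prior, prior_cpm, 0.0)
    fc_den = mean_den + np.where(needs_prior, prior_cpm, 0.0)

    all_zero = (df.sum(axis=1) == 0).to_numpy()
    pvals = np.ones(len(df))
    for i in range(len(df)):
        if not all_zero[i]:
            pvals[i] = _exact_p(int(z_num.iloc[i]), int(z_den.iloc[i]), n_num, n_den, dispersion)

    fc = np.where(all_zero, 1.0, fc_num / fc_den)
    res = pd.DataFrame(
        {
            "mean_den": mean_den,
            "mean_num": mean_num,
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
            "p_value": pvals,
            "all_zero": all_zero,
        },
        index=df.index,
    )
    res["fdr"] = stats.false_discovery_control(res["p_value"].to_numpy(), method="bh")
    res.attrs["numerator"] = numerator
    res.attrs["denominator"] = denominator
    return res


def call_de(results: pd.DataFrame, p_cutoff: float = 0.05, fc_cutoff: float = 1.5
            ) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Apply the selection rule p < p_cutoff and max(FC, 1/FC) > fc_cutoff.

    Returns the annotated table plus the called sets split by direction
    (up = fold-change above 1 in the numerator group).
    """
    if results.empty:
        raise DataError("empty result table")
    res = results.copy()
    fc = res["fold_change"].to_numpy(dtype=float)
    sym_fc = np.maximum(fc, 1.0 / fc)
    res["called"] = (res["p_value"].to_numpy() < p_cutoff) & (sym_fc > fc_cutoff)
    res["direction"] = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    up = set(res.index[res["called"] & (res["direction"] == "up")])
    down = set(res.index[res["called"] & (res["direction"] == "down")])
    return res, up, down


def ev_partition(ev_counts: CountMatrix, evd_counts: CountMatrix,
                 p_cutoff: float = 0.05, fc_cutoff: float = 1.5,
                 dispersion: float | None = None) -> tuple[set[str], set[str], pd.DataFrame]:
    """Split common features into EV-enriched and EV-underrepresented sets.

    Runs the same TMM + common-dispersion exact-test machinery with plasma
    fraction as the grouping variable, on the features detected in both
    fractions. Fold-change orientation is EV over EVD.
    """
    common = ev_counts.counts.index.intersection(evd_counts.counts.index)
    if len(common) == 0:
        raise DataError("no features detected in both fractions")
    joint = pd.concat([ev_counts.counts.loc[common], evd_counts.counts.loc[common]], axis=1)
    groups = pd.Series(
        ["EV"] * ev_counts.counts.shape[1] + ["EVD"] * evd_counts.counts.shape[1],
        index=joint.columns,
    )
    factors = tmm_factors(joint)
    if dispersion is None:
        dispersion = estimate_common_dispersion(joint, groups, factors)
    res = nb_exact_test(joint, groups, factors, dispersion, numerator="EV", denominator="EVD")
    res, enriched, underrepresented = call_de(res, p_cutoff, fc_cutoff)
    return enriched, underrepresented, res


# ---------------------------------------------------------------------------
# EV-sorting motif scan
# ---------------------------------------------------------------------------

@dataclass
class MotifReport:
    """Per-feature 3'-end motif hits and set-level counts."""

    per_feature: pd.DataFrame  # sequence, has_GGAG, has_GGCU, hit
    mode: str
    n_scanned: int
    n_missing: int
    motif_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_hits(self) -> int:
        return int(self.per_feature["hit"].sum())


def motif_scan(sequences: pd.Series, feature_set, motifs: tuple[str, ...] = ("GGAG", "GGCU"),
               mode: str = "suffix", window_nt: int = 6) -> MotifReport:
    """Scan a feature set's mature sequences for 3'-end sorting motifs.

    ``suffix`` mode requires the motif to be the terminal 4 nt; ``window``
    mode accepts it anywhere within the last ``window_nt`` nucleotides. DNA
    input is converted to RNA (T -> U). Features without a sequence are
    skipped with a warning and counted in ``n_missing``.
    """
    if mode not in ("suffix", "window"):
        raise ConfigError(f"unknown motif scan mode {mode!r}")
    rows = []
    missing = []
    for feat in feature_set:
        if feat not in sequences.index or not isinstance(sequences.get(feat), str):
            missing.append(feat)
            continue
        seq = sequences[feat].upper().replace("T", "U")
        hits = {}
        for motif in motifs:
            if mode == "suffix":
                hits[motif] = seq.endswith(motif)
            else:
                hits[motif] = motif in seq[-window_nt:]
        rows.append({"feature": feat, "sequence": seq,
                     **{f"has_{m}": h for m, h in hits.items()},
                     "hit": any(hits.values())})
    if missing:
        warnings.warn(f"{len(missing)} feature(s) without sequences skipped", stacklevel=2)
    per_feature = pd.DataFrame(rows, columns=["feature", "sequence",
                                              *[f"has_{m}" for m in motifs], "hit"])
    if len(per_feature):
        per_feature = per_feature.set_index("feature")
    motif_counts = {m: int(per_feature[f"has_{m}"].sum()) if len(per_feature) else 0 for m in motifs}
    return MotifReport(per_feature=per_feature, mode=mode,
                       n_scanned=len(per_feature), n_missing=len(missing),
                       motif_counts=motif_counts)
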