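"""Nonparametric statistical battery for the cohort comparisons.

Three families of tests, mirroring the study design the package serves:

* tissue — connective tissue vs myocytes, for fibre density and each of the
  7 marker-combination frequencies (Mann-Whitney U, alpha = .05);
* sex — men vs women, same quantities, on combined and per-tissue data
  (Mann-Whitney U, alpha = .05);
* age — Spearman correlation of age with each combined combination
  frequency, per sex, judged at the Bonferroni-adjusted level
  alpha / 7 (one test per combination; .05/7 ~ .007).

Two-sided p-values throughout. Exact Mann-Whitney p-values are obtained by
enumeration of rank splits for small tie-free samples; ties in exact mode
fall back to exhaustive permutation conditional on the observed tie pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .colocalization import COMBINATIONS
from .config import TISSUES, PipelineConfig
from .quantify import ParticipantSummary

__all__ = [
    "StatResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "spearman",
    "bonferroni_alpha",
    "run_study_battery",
    "battery_frame",
]


@dataclass
class StatResult:
    """One test: statistic, p-value, threshold and decision."""

    name: str
    family: str
    test: str
    groups: str
    n1: int
    n2: int
    statistic: float
    p_value: float
    alpha_adjusted: float
    error: str | None = None

    @property
    def significant(self) -> bool:
        return self.error is None and self.p_value < self.alpha_adjusted


def _as_clean_array(x) -> np.ndarray:
    a = np.asarray(list(x), dtype=float)
    return a[~np.isnan(a)]


def mann_whitney(
    sample_a,
    sample_b,
    mode: str = "auto",
    alpha: float = 0.05,
    name: str = "mann_whitney",
    family: str = "",
) -> StatResult:
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` enumerates all rank assignments (exhaustive permutation
    when ties are present); ``"approx"`` uses the normal approximation with
    tie-corrected variance and continuity correction; ``"auto"`` picks exact
    for tie-free samples with n1 + n2 <= 14, the approximation otherwise.
    The reported U is the statistic of the first sample, so
    U(a, b) + U(b, a) = n1 * n2.
    """
    a = _as_clean_array(sample_a)
    b = _as_clean_array(sample_b)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("Mann-Whitney requires two non-empty samples")

    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if np.ptp(pooled) == 0:
        # all observations identical: complete overlap, no evidence at all
        return StatResult(name, family, "mann_whitney", "a vs b", n1, n2,
                          statistic=n1 * n2 / 2.0, p_value=1.0,
                          alpha_adjusted=alpha)

    if mode == "exact" or (mode == "auto" and not has_ties and n1 + n2 <= 14):
        if has_ties:
            # exact conditional on the observed tie pattern: exhaustive
            # permutation over group assignments
            n_splits = comb(n1 + n2, n1)
            method = sps.PermutationMethod(n_resamples=max(n_splits + 1, 9999))
        else:
            method = "exact"
    elif mode in ("approx", "auto"):
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return StatResult(name, family, "mann_whitney", "a vs b", n1, n2,
                      statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      alpha_adjusted=alpha)


def wilcoxon_signed_rank(
    sample_a, sample_b, alpha: float = 0.05,
    name: str = "wilcoxon", family: str = "",
) -> StatResult:
    """Paired signed-rank alternative for the tissue comparison."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need >= 2 complete pairs")
    if np.all(a == b):
        return StatResult(name, family, "wilcoxon", "a vs b", len(a), len(b),
                          statistic=0.0, p_value=1.0, alpha_adjusted=alpha)
    res = sps.wilcoxon(a, b, alternative="two-sided")
    return StatResult(name, family, "wilcoxon", "a vs b", len(a), len(b),
                      statistic=float(res.statistic), p_value=float(res.pvalue),
                      alpha_adjusted=alpha)


def spearman(
    x,
    y,
    method: str = "t",
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    name: str = "spearman",
    family: str = "",
) -> StatResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (tie-aware). ``method="t"``
    uses the t-distribution approximation; ``method="permutation"`` estimates
    the p-value from ``n_permutations`` random permutations (recommended for
    n < 15).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("Spearman requires equal-length samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for zero-variance input")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "permutation":
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        perms = np.argsort(rng.random((n_permutations, n)), axis=1)
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        null_rho = (ry_c[perms] @ rx_c) / denom
        # add-one estimator keeps the permutation p-value valid
        p = (1 + np.sum(np.abs(null_rho) >= abs(rho) - 1e-12)) / (n_permutations + 1)
    elif method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")

    return StatResult(name, family, "spearman", "x vs y", n, n,
                      statistic=rho, p_value=float(min(p, 1.0)),
                      alpha_adjusted=alpha)


def bonferroni_alpha(alpha: float, m: int) -> tuple[float, float]:
    """Bonferroni-adjusted per-test threshold alpha / m.

    Returns the exact value and the value rounded to three decimals as
    reported (0.05 over 7 tests -> 0.00714..., reported as .007).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    adjusted = alpha / m
    return adjusted, round(adjusted, 3)


# ---------------------------------------------------------------------------
# the study battery
# ---------------------------------------------------------------------------

_QUANTITIES = ("density",) + COMBINATIONS


def _values(summaries, scope: str, quantity: str) -> np.ndarray:
    out = []
    for s in summaries:
        if scope in TISSUES and scope not in s.tissues_present:
            continue
        v = s.densities[scope] if quantity == "density" else s.frequencies[scope][quantity]
        if v is not None:
            out.append(v)
    return np.asarray(out, dtype=float)


def run_study_battery(
    summaries: list[ParticipantSummary],
    config: PipelineConfig | None = None,
) -> list[StatResult]:
    """Run the full between-tissue / between-sex / age-correlation battery.

    Mann-Whitney comparisons are judged at ``alpha``; the age Spearman
    correlations at the Bonferroni-adjusted ``alpha / n_family_tests``.
    Tests whose groups are too small are recorded with an ``error`` and the
    battery continues.
    """
    cfg = config or PipelineConfig()
    alpha = cfg.alpha
    alpha_age, _ = bonferroni_alpha(alpha, cfg.n_family_tests)
    rng = np.random.default_rng(cfg.seed)
    results: list[StatResult] = []

    def _record(fn, name, family, **kw):
        try:
            results.append(fn(**kw, name=name, family=family))
        except ValueError as exc:
            results.append(StatResult(name, family, kw.get("test", ""), "", 0, 0,
                                      np.nan, np.nan, alpha, error=str(exc)))

    # (a) connective tissue vs myocytes
    for q in _QUANTITIES:
        a = _values(summaries, "connective", q)
        b = _values(summaries, "myocyte", q)
        name = f"tissue:{q}"
        if cfg.tissue_test == "wilcoxon":
            paired_a, paired_b = _paired_tissue_values(summaries, q)
            _record(wilcoxon_signed_rank, name, "tissue",
                    sample_a=paired_a, sample_b=paired_b, alpha=alpha)
        else:
            _record(mann_whitney, name, "tissue",
                    sample_a=a, sample_b=b, mode=cfg.mw_mode, alpha=alpha)

    # (b) men vs women, per scope
    men = [s for s in summaries if s.sex == "M"]
    women = [s for s in summaries if s.sex == "F"]
    for scope in ("combined",) + TISSUES:
        for q in _QUANTITIES:
            _record(mann_whitney, f"sex:{scope}:{q}", "sex",
                    sample_a=_values(men, scope, q),
                    sample_b=_values(women, scope, q),
                    mode=cfg.mw_mode, alpha=alpha)

    # (c) age vs combined frequencies, per sex, Bonferroni over the 7 tests
    for sex_name, group in (("women", women), ("men", men)):
        for c in COMBINATIONS:
            pairs = [
                (s.age, s.frequencies["combined"][c])
                for s in group
                if s.frequencies["combined"][c] is not None
            ]
            name = f"age:{sex_name}:{c}"
            if len(pairs) < 4:
                results.append(StatResult(name, "age", "spearman", "", len(pairs),
                                          len(pairs), np.nan, np.nan, alpha_age,
                                          error="fewer than 4 complete pairs"))
                continue
            ages, freqs = map(np.asarray, zip(*pairs))
            use_perm = cfg.spearman_permutations > 0 and len(pairs) < 15
            _record(
                spearman, name, "age",
                x=ages, y=freqs,
                method="permutation" if use_perm else "t",
                n_permutations=max(cfg.spearman_permutations, 1),
                rng=rng, alpha=alpha_age,
            )
    return results


def _paired_tissue_values(summaries, quantity):
    a, b = [], []
    for s in summaries:
        va = (s.densities["connective"] if quantity == "density"
              else s.frequencies["connective"][quantity])
        vb = (s.densities["myocyte"] if quantity == "density"
              else s.frequencies["myocyte"][quantity])
        if va is not None and vb is not None:
            a.append(va)
            b.append(vb)
    return a, b


def battery_frame(results: list[StatResult]) -> pd.DataFrame:
    """Statistics report: one row per test."""
    return pd.DataFrame(
        {
            "name": r.name,
            "family": r.family,
            "test": r.test,
            "n1": r.n1,
            "n2": r.n2,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "alpha_adjusted": r.alpha_adjusted,
            "significant": r.significant,
            "error": r.error or "",
        }
        for r in results
    )
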