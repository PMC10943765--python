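"""Trait-table statistics for harvest-period ranking.

Per-plant morphological traits (X1-X9: stem length, fresh/dry stem and leaf
weights, stem/leaf dry matter content and water content) are summarised
month by month: coefficients of variation flag unstable traits, a
correlation-matrix factor analysis with varimax rotation condenses the nine
traits into a few interpretable factors whose weighted scores rank the
months, and Spearman correlations link the traits to solar radiation and
precipitation over the harvest window.

Dry matter content (DMC, %) is dry weight / fresh weight x 100; water
content is its exact complement (100 - DMC).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "TRAIT_COLUMNS",
    "cv",
    "dmc",
    "water_content",
    "monthly_cv_table",
    "TraitFactorModel",
    "FactorResult",
    "factor_analysis",
    "spearman_env",
    "rank_harvest_months",
    "validate_trait_table",
]

TRAIT_COLUMNS = ["X1", "X2", "X3", "X4", "X5", "X6", "X7", "X8", "X9"]

#: printed trait values satisfy the DMC/water complements to this tolerance
COMPLEMENT_TOL = 0.1


def cv(values) -> float:
    """Coefficient of variation: sample standard deviation / mean."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean == 0.0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def dmc(dry_weight: float, fresh_weight: float) -> float:
    """Dry matter content in %: dry / fresh x 100."""
    if fresh_weight <= 0:
        raise ValueError(f"fresh weight must be positive, got {fresh_weight}")
    if dry_weight < 0:
        raise ValueError(f"dry weight must be non-negative, got {dry_weight}")
    if dry_weight > fresh_weight:
        warnings.warn("dry weight exceeds fresh weight; DMC > 100%", stacklevel=2)
    return dry_weight / fresh_weight * 100.0


def water_content(dmc_pct: float) -> float:
    """Water content in %, the exact complement of dry matter content."""
    if not 0.0 <= dmc_pct <= 100.0:
        raise ValueError(f"DMC must be in [0, 100], got {dmc_pct}")
    return 100.0 - dmc_pct


def _trait_columns(t: pd.DataFrame) -> list[str]:
    return [c for c in TRAIT_COLUMNS if c in t.columns]


def validate_trait_table(t: pd.DataFrame) -> None:
    """Check the month column, at least one trait, and the DMC/water
    complement identities for whichever complement pairs are present."""
    if "month" not in t.columns:
        raise ValueError("trait table needs a 'month' column")
    if not _trait_columns(t):
        raise ValueError(f"trait table has none of the trait columns {TRAIT_COLUMNS}")
    for a, b in (("X6", "X8"), ("X7", "X9")):
        if a not in t.columns or b not in t.columns:
            continue
        dev = (t[a] + t[b] - 100.0).abs().max()
        if dev > COMPLEMENT_TOL + 1e-9:
            raise ValueError(
                f"{a}+{b} deviates from 100 by {dev:.3f} (> {COMPLEMENT_TOL})"
            )


def monthly_cv_table(t: pd.DataFrame, flag_threshold: float = 0.20) -> pd.DataFrame:
    """CV of every trait within every month, with instability flags.

    Returns a months x traits table of CVs; the companion boolean table of
    cells exceeding ``flag_threshold`` is attached as ``.attrs['unstable']``.
    """
    validate_trait_table(t)
    rows = {}
    for month, g in t.groupby("month"):
        if len(g) < 2:
            raise ValueError(f"month {month} has fewer than 2 plants")
        rows[month] = {c: cv(g[c]) for c in _trait_columns(t)}
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "month"
    out.attrs["unstable"] = out > flag_threshold
    return out


# ---------------------------------------------------------------------------
# factor analysis
# ---------------------------------------------------------------------------

@dataclass
class FactorResult:
    """Principal-factor extraction with varimax rotation and month ranking.

    contributions are the per-factor explained-variance percentages after
    rotation; composite scores weight each month's mean factor scores by
    contribution / cumulative contribution.
    """

    eigenvalues: np.ndarray
    contributions: np.ndarray
    cumulative_contribution: float
    loadings: pd.DataFrame = field(repr=False)
    month_scores: pd.DataFrame = field(repr=False)
    composite_scores: pd.Series = field(repr=False)
    ranking: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return len(self.contributions)

    def summary(self) -> str:
        lines = [
            f"Factor analysis: {self.n_factors} factors, "
            f"cumulative contribution {self.cumulative_contribution:.2f}%",
            "  contributions (%): "
            + ", ".join(f"{c:.2f}" for c in self.contributions),
            "  month ranking (best first): "
            + " > ".join(str(m) for m in self.ranking),
        ]
        return "\n".join(lines)


class TraitFactorModel:
    """Model object: trait table in, rotated factor solution out.

    Extraction is a principal-component decomposition of the trait
    correlation matrix (so results are invariant to affine rescaling of any
    trait); retained factors default to eigenvalue > 1.  Loadings are
    varimax-rotated and factor scores computed by the regression method.
    The trait complements (water content = 100 - DMC) make the correlation
    matrix exactly rank-deficient; scores therefore use a pseudo-inverse,
    which is the least-squares regression solution on the degenerate matrix.
    """

    def __init__(self, traits: pd.DataFrame):
        validate_trait_table(traits)
        self.traits = traits.reset_index(drop=True)

    def fit(self, n_factors: int | None = None) -> FactorResult:
        t = self.traits
        cols = _trait_columns(t)
        x = t[cols].to_numpy(float)
        sd = x.std(axis=0, ddof=1)
        dead = [c for c, s in zip(cols, sd) if s == 0.0]
        if dead:
            raise ValueError(f"traits with zero variance: {dead}")
        z = (x - x.mean(axis=0)) / sd
        r = np.atleast_2d(np.corrcoef(x, rowvar=False))
        eigvals, eigvecs = np.linalg.eigh(r)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        eigvals = np.clip(eigvals, 0.0, None)
        k = n_factors if n_factors is not None else max(int(np.sum(eigvals > 1.0)), 1)
        k = min(k, len(cols))

        loadings = eigvecs[:, :k] * np.sqrt(eigvals[:k])
        if k > 1:
            loadings, _ = rotate_factors(loadings, "varimax")
        # sign convention: dominant loading of each factor positive
        signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
        signs[signs == 0] = 1.0
        loadings = loadings * signs
        # order factors by explained variance after rotation
        contrib = (loadings ** 2).sum(axis=0) / len(cols) * 100.0
        f_order = np.argsort(contrib)[::-1]
        loadings, contrib = loadings[:, f_order], contrib[f_order]
        cumulative = float(contrib.sum())

        scores = z @ np.linalg.pinv(r) @ loadings  # regression-method scores
        score_df = pd.DataFrame(scores, columns=[f"F{i+1}" for i in range(k)])
        score_df["month"] = t["month"].to_numpy()
        month_scores = score_df.groupby("month").mean()
        weights = contrib / cumulative
        composite = pd.Series(
            month_scores.to_numpy() @ weights, index=month_scores.index,
            name="composite",
        )
        ranking = list(composite.sort_values(ascending=False).index)
        return FactorResult(
            eigenvalues=eigvals,
            contributions=contrib,
            cumulative_contribution=cumulative,
            loadings=pd.DataFrame(
                loadings, index=cols,
                columns=[f"F{i+1}" for i in range(k)],
            ),
            month_scores=month_scores,
            composite_scores=composite,
            ranking=ranking,
        )


def factor_analysis(t: pd.DataFrame, n_factors: int | None = None) -> FactorResult:
    """Functional wrapper over :class:`TraitFactorModel`."""
    return TraitFactorModel(t).fit(n_factors=n_factors)


# ---------------------------------------------------------------------------
# environment correlations
# ---------------------------------------------------------------------------

def _spearman_exact_p(a: np.ndarray, b: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (n <= 8)."""
    n = len(a)
    rb = stats.rankdata(b)
    count, total = 0, 0
    for perm in itertools.permutations(range(n)):
        ra = stats.rankdata(a[list(perm)])
        rho = np.corrcoef(ra, rb)[0, 1]
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_env(traits: pd.DataFrame, env: pd.DataFrame,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of monthly trait means with environment columns.

    ``env`` must hold columns month, sard, pre.  For n <= 8 paired months the
    two-sided p-value is an exact permutation probability; for larger n the
    t-approximation is used.  Returns a long-format table with columns
    trait, variable, rho, p, significant; constant traits give missing rho.
    """
    validate_trait_table(traits)
    for c in ("month", "sard", "pre"):
        if c not in env.columns:
            raise ValueError(f"environment table is missing column {c!r}")
    monthly = traits.groupby("month")[_trait_columns(traits)].mean()
    merged = monthly.join(env.set_index("month")[["sard", "pre"]], how="inner")
    n = len(merged)
    if n < 3:
        raise ValueError("need at least 3 paired months")
    rows = []
    for trait in _trait_columns(traits):
        a = merged[trait].to_numpy()
        for var in ("sard", "pre"):
            b = merged[var].to_numpy()
            if np.all(a == a[0]) or np.all(b == b[0]):
                rows.append({"trait": trait, "variable": var,
                             "rho": np.nan, "p": np.nan, "significant": False})
                continue
            rho = float(stats.spearmanr(a, b).statistic)
            if n <= 8:
                p = _spearman_exact_p(a, b, rho)
            else:
                p = float(stats.spearmanr(a, b).pvalue)
            rows.append({"trait": trait, "variable": var, "rho": rho, "p": p,
                         "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# harvest ranking
# ---------------------------------------------------------------------------

def rank_harvest_months(f: FactorResult, traits: pd.DataFrame,
                        cv_flag_threshold: float = 0.20) -> pd.DataFrame:
    """Compose factor ranking, monthly DMC and CV stability into a report.

    The "suitable window" collects months ranking in the top half of the
    composite scores or whose leaf DMC exceeds the annual mean; the
    "optimal" month maximises leaf DMC within that window.  These rules are
    an explicit, configurable heuristic (see the methods note), not a
    statistical test.
    """
    validate_trait_table(traits)
    months = sorted(traits["month"].unique())
    if len(months) != 12:
        raise ValueError("harvest ranking expects all 12 months present")
    dmc_stem = traits.groupby("month")["X6"].mean()
    dmc_leaf = traits.groupby("month")["X7"].mean()
    cvs = monthly_cv_table(traits, flag_threshold=cv_flag_threshold)
    n_unstable = cvs.attrs["unstable"].sum(axis=1)

    report = pd.DataFrame({
        "month": months,
        "composite_score": [f.composite_scores.get(m, np.nan) for m in months],
        "composite_rank": [f.ranking.index(m) + 1 if m in f.ranking else np.nan
                           for m in months],
        "dmc_stem": dmc_stem.reindex(months).to_numpy(),
        "dmc_leaf": dmc_leaf.reindex(months).to_numpy(),
        "n_unstable_traits": n_unstable.reindex(months).to_numpy(),
    })
    # months are indistinguishable when every trait's monthly means are flat
    # relative to the trait's own magnitude (checked on the raw scale; the
    # standardised factor scores would amplify arbitrarily small jitter)
    monthly_means = traits.groupby("month")[_trait_columns(traits)].mean()
    rel_range = ((monthly_means.max() - monthly_means.min())
                 / monthly_means.abs().mean().clip(lower=1e-12))
    if (rel_range < 1e-6).all():
        report["in_window"] = False
        report["optimal"] = False
        report.attrs["note"] = "months are indistinguishable; no distinct window"
        return report
    top_half = report["composite_rank"] <= len(months) / 2
    high_dmc = report["dmc_leaf"] > report["dmc_leaf"].mean()
    report["in_window"] = top_half | high_dmc
    window = report[report["in_window"]]
    optimal = window.loc[window["dmc_leaf"].idxmax(), "month"]
    report["optimal"] = report["month"] == optimal
    report.attrs["note"] = (
        f"suitable window: months {sorted(window['month'].tolist())}; "
        f"optimal month: {optimal}"
    )
    return report
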