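"""Per-sample bias summaries and group-level inference.

The per-sample quantity of interest is the *proximity-bias delta*:
observed minus expected-null median (or mean) distance of marker-positive
cells to the nearest stroma, in microns.  Negative deltas mean positives
concentrate near stroma.  Within a treatment group the observed-vs-
predicted comparison is a paired two-tailed t-test, analyzed as a
one-sample t-test on the per-tumor deltas (algebraically identical).
Between two host models the comparison is the interaction term of a
fixed-effects two-way ANOVA on the long observed/predicted table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import avatar as avatar_null
from . import metrics
from .io import TissueSample

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # reported when a degenerate zero-variance test underflows


@dataclass
class BiasSummary:
    """Observed-vs-null spatial bias statistics for one tumor cross-section."""

    sample_id: str
    treatment: str
    host_model: str
    n_cells: int
    n_positive: int
    observed_median: float
    observed_mean: float
    null_median: float
    null_mean: float
    delta_median: float
    delta_mean: float
    ks_d: float
    p_left: float
    r: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BiasSummary":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class PairedResult:
    """Paired observed-vs-predicted t-test within one group."""

    t: float
    p: float
    n_pairs: int
    statistic: str
    degenerate: bool = False


@dataclass
class InteractionResult:
    """Interaction term of the two-way (model x condition) ANOVA."""

    f: float
    p: float
    statistic: str
    n_samples: int


@dataclass
class GroupResult:
    """Inference for a set of samples sharing group labels."""

    summaries: list
    paired: dict
    interaction: dict | None = None


def sample_bias(sample: TissueSample, r: int = 1000, seed: int | None = None) -> BiasSummary:
    """Compute one sample's :class:`BiasSummary`.

    Observed statistics come from the marker-positive cells; the predicted
    (null) median/mean use the closed-form expectation over avatars (the
    all-cell summary), while the R-replicate avatar ensemble provides the
    left-tail empirical p-value of the observed positive median.
    """
    profile = metrics.cell_distances(sample)
    if profile.k == 0:
        raise ValueError(f"{sample.sample_id}: no marker-positive cells")
    obs_median, obs_mean, _ = metrics.summarize(profile, "positive")
    null_median, null_mean = avatar_null.expected_null_summary(profile)
    ks_d, _ = metrics.ks_statistic(profile.positive_distances, profile.distances)
    ensemble = avatar_null.null_ensemble(profile, r=r, seed=seed)
    p_left = avatar_null.empirical_pvalue(obs_median, ensemble.medians, tail="left")
    return BiasSummary(
        sample_id=sample.sample_id,
        treatment=sample.treatment,
        host_model=sample.host_model,
        n_cells=profile.n,
        n_positive=profile.k,
        observed_median=obs_median,
        observed_mean=obs_mean,
        null_median=null_median,
        null_mean=null_mean,
        delta_median=obs_median - null_median,
        delta_mean=obs_mean - null_mean,
        ks_d=ks_d,
        p_left=p_left,
        r=r,
        seed=seed,
    )


def _deltas(summaries, statistic: str) -> np.ndarray:
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    attr = f"delta_{statistic}"
    return np.array([getattr(s, attr) for s in summaries], dtype=float)


def paired_observed_vs_predicted(summaries, statistic: str = "median") -> PairedResult:
    """Two-tailed paired t-test of observed vs predicted values, run as a
    one-sample t-test of the per-sample deltas against zero.

    All-zero deltas return ``t=0, p=1`` by convention.  Zero variance with
    a nonzero mean has an infinite t; p is reported at an underflow floor
    and the result flagged degenerate.
    """
    deltas = _deltas(summaries, statistic)
    n = deltas.size
    if n < 2:
        raise ValueError("paired test needs at least 2 samples")
    if np.all(deltas == 0):
        return PairedResult(t=0.0, p=1.0, n_pairs=n, statistic=statistic)
    sd = deltas.std(ddof=1)
    if sd == 0:
        warnings.warn(
            "zero-variance deltas with nonzero mean: t is infinite, "
            "p reported at floor",
            stacklevel=2,
        )
        return PairedResult(
            t=float(np.sign(deltas.mean()) * np.inf),
            p=_P_FLOOR,
            n_pairs=n,
            statistic=statistic,
            degenerate=True,
        )
    res = stats.ttest_1samp(deltas, 0.0)
    return PairedResult(t=float(res.statistic), p=float(res.pvalue), n_pairs=n, statistic=statistic)


def long_table(summaries, statistic: str = "median") -> pd.DataFrame:
    """Tidy observed/predicted table: one row per sample x condition."""
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    rows = []
    for s in summaries:
        rows.append(
            {"sample_id": s.sample_id, "model": s.host_model, "treatment": s.treatment,
             "condition": "observed", "value": getattr(s, f"observed_{statistic}")}
        )
        rows.append(
            {"sample_id": s.sample_id, "model": s.host_model, "treatment": s.treatment,
             "condition": "predicted", "value": getattr(s, f"null_{statistic}")}
        )
    return pd.DataFrame(rows)


def interaction_test(summaries, statistic: str = "median") -> InteractionResult:
    """Host-model x condition interaction from a fixed-effects two-way ANOVA.

    Tests whether the observed-vs-predicted difference itself differs
    between the two host models, i.e. whether the spatial proliferation
    bias depends on the model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    table = long_table(summaries, statistic)
    models = sorted(table["model"].unique())
    if len(models) != 2:
        raise ValueError(f"interaction test needs exactly 2 host models, got {models}")
    for m in models:
        n_m = (table["model"] == m).sum() // 2
        if n_m < 2:
            raise ValueError(f"host model {m!r} has {n_m} sample(s); need >= 2")
    fit = smf.ols("value ~ C(model) * C(condition)", data=table).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    row = anova.loc["C(model):C(condition)"]
    f = float(row["F"])
    p = float(row["PR(>F)"])
    if not np.isfinite(f):  # interaction SS ~ 0 with ~0 residual
        f, p = 0.0, 1.0
    return InteractionResult(f=f, p=p, statistic=statistic, n_samples=len(summaries))


def compare_groups(summaries, statistic: str = "median") -> GroupResult:
    """Run the full group-level comparison on a list of summaries.

    Per (treatment, model) group: the paired observed-vs-predicted test.
    If exactly two host models are present, the interaction test is added.
    """
    paired = {}
    key = lambda s: (s.treatment, s.host_model)
    groups = sorted({key(s) for s in summaries})
    for g in groups:
        members = [s for s in summaries if key(s) == g]
        if len(members) < 2:
            raise ValueError(f"group {g} has {len(members)} sample(s); need >= 2")
        res = paired_observed_vs_predicted(members, statistic)
        paired["/".join(filter(None, g)) or "all"] = asdict(res)
    models = sorted({s.host_model for s in summaries})
    interaction = None
    if len(models) == 2:
        interaction = asdict(interaction_test(summaries, statistic))
    return GroupResult(summaries=list(summaries), paired=paired, interaction=interaction)
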