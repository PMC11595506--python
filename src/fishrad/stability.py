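"""Feature-stability analysis across preprocessing conditions.

For each feature i and mask j, the deviation of a candidate
preprocessing condition from the original-resolution reference is the
magnitude of the relative percentage error

    delta_ij = |v_obs - v_ref| / |v_ref| * 100 .

Per-feature means delta_i (over masks) and the grand mean M (over
features) summarize a condition; features whose reference value is 0
while the observed value is not are *excluded* from the means (an
infinite error would otherwise dominate M) and reported separately.
Conditions are compared feature-wise (win counts on delta_i) and with a
classical two-tailed paired t-test on the delta_i vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError
from .features import extract_study
from .preprocess import PreprocessSpec
from .study import FeatureTable, StudyManifest

logger = logging.getLogger("fishrad.stability")

__all__ = [
    "ErrorMatrix",
    "StabilityReport",
    "ConditionComparison",
    "relative_error",
    "error_matrix",
    "summarize",
    "compare_conditions",
    "stability_experiment",
]

DEFAULT_FLAG_THRESHOLD = 2.0  # percent


def relative_error(observed: float, reference: float) -> float:
    """|observed - reference| / |reference| * 100, or NaN when undefined.

    A zero reference with a zero observation is a perfect match (0%);
    a zero reference with a nonzero observation has no defined relative
    error and is tagged NaN for exclusion upstream.
    """
    if reference == 0.0:
        return 0.0 if observed == 0.0 else float("nan")
    return abs(observed - reference) / abs(reference) * 100.0


@dataclass
class ErrorMatrix:
    """Per-(feature, mask) relative percentage errors; NaN = excluded."""

    delta: pd.DataFrame  # rows = features, columns = (specimen, region) keys

    @property
    def n_features(self) -> int:
        return len(self.delta)

    @property
    def n_masks(self) -> int:
        return self.delta.shape[1]

    @property
    def excluded(self) -> pd.DataFrame:
        return self.delta.isna()


@dataclass
class StabilityReport:
    """Aggregated deviation of one condition from the reference."""

    condition: str
    delta_i: pd.Series  # per-feature mean over masks (NaN if fully excluded)
    M: float
    n_features: int
    n_masks: int
    flag_threshold: float
    flagged: list[str] = field(default_factory=list)
    excluded_features: list[str] = field(default_factory=list)


@dataclass
class ConditionComparison:
    a: str
    b: str
    M_a: float
    M_b: float
    wins_a: int  # features where delta_i(a) < delta_i(b)
    wins_b: int
    ties: int
    n: int
    t_statistic: float
    p_value: float


def error_matrix(cond: FeatureTable, ref: FeatureTable) -> ErrorMatrix:
    """Element-wise relative percentage error between paired tables.

    Both tables must cover the same (specimen, region) keys and feature
    inventory; rows are matched by key, not order.
    """
    key_cols = ["specimen", "region"]
    if cond.feature_names != ref.feature_names:
        raise PairingError("feature inventories differ between tables")
    ck = cond.data.set_index(key_cols)
    rk = ref.data.set_index(key_cols)
    missing = rk.index.difference(ck.index).tolist()
    extra = ck.index.difference(rk.index).tolist()
    if missing or extra:
        raise PairingError(
            f"unmatched (specimen, region) keys: missing={missing} extra={extra}"
        )
    ck = ck.loc[rk.index]
    feats = ref.feature_names
    obs = ck[feats].to_numpy(dtype=float).T  # features x masks
    refv = rk[feats].to_numpy(dtype=float).T
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.abs(obs - refv) / np.abs(refv) * 100.0
    delta = np.where(refv == 0.0, np.where(obs == 0.0, 0.0, np.nan), delta)
    cols = [f"{s}/{r}" for s, r in rk.index]
    return ErrorMatrix(pd.DataFrame(delta, index=feats, columns=cols))


def summarize(
    errors: ErrorMatrix,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
    condition: str = "",
) -> StabilityReport:
    """Per-feature means delta_i, grand mean M, and flagged features.

    delta_i is the mean over the *defined* entries of feature i; a
    feature with no defined entry is dropped from M and listed under
    ``excluded_features``.
    """
    delta_i = errors.delta.mean(axis=1, skipna=True)
    excluded = delta_i[delta_i.isna()].index.tolist()
    included = delta_i.dropna()
    m = float(included.mean()) if len(included) else 0.0
    flagged = included[included > flag_threshold].index.tolist()
    return StabilityReport(
        condition=condition,
        delta_i=delta_i,
        M=m,
        n_features=errors.n_features,
        n_masks=errors.n_masks,
        flag_threshold=flag_threshold,
        flagged=flagged,
        excluded_features=excluded,
    )


def compare_conditions(a: StabilityReport, b: StabilityReport) -> ConditionComparison:
    """Feature-wise win counts and a paired two-tailed t-test on delta_i.

    The test is run on the per-feature mean errors (one paired value per
    feature), restricted to features defined in both reports.  Zero
    variance of the differences degenerates to p = 1 when all
    differences are 0 and to p = 0 otherwise (infinite t).
    """
    if list(a.delta_i.index) != list(b.delta_i.index):
        raise PairingError("feature inventories differ between reports")
    da = a.delta_i
    db = b.delta_i
    both = da.notna() & db.notna()
    diffs = (da[both] - db[both]).to_numpy()
    wins_a = int((da[both] < db[both]).sum())
    wins_b = int((db[both] < da[both]).sum())
    ties = int(both.sum()) - wins_a - wins_b
    if len(diffs) < 2 or np.all(diffs == 0.0):
        t_stat, p = 0.0, 1.0
    elif np.std(diffs) == 0.0:
        t_stat = float(np.inf if diffs[0] > 0 else -np.inf)
        p = 0.0
    else:
        t_stat, p = stats.ttest_1samp(diffs, 0.0)
        t_stat, p = float(t_stat), float(p)
    return ConditionComparison(
        a=a.condition, b=b.condition, M_a=a.M, M_b=b.M,
        wins_a=wins_a, wins_b=wins_b, ties=ties, n=int(both.sum()),
        t_statistic=t_stat, p_value=p,
    )


def _subset_keys(table: FeatureTable, keys: pd.DataFrame) -> FeatureTable:
    sub = pd.merge(keys, table.data, how="left", on=["specimen", "region"])
    return FeatureTable(sub, dict(table.settings))


def _condition_name(spec: PreprocessSpec) -> str:
    name = spec.mode
    if spec.mode != "none":
        name += f"-{spec.reduction_factor:g}"
    name += f"-bins{spec.bin_count}"
    return name


def stability_experiment(
    manifest: StudyManifest,
    conditions: list[PreprocessSpec],
    ref_spec: PreprocessSpec | None = None,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
    out_dir=None,
) -> tuple[list[StabilityReport], list[ConditionComparison]]:
    """Run the full resolution analysis on a study.

    A reference table is extracted at original size for every bin count
    appearing among the conditions (matching each condition against the
    reference that shares its discretization), every condition is
    extracted and summarized, and all pairwise comparisons are computed.
    CSV reports are written to ``out_dir`` when given.
    """
    references: dict[tuple, FeatureTable] = {}
    reports: list[StabilityReport] = []
    for cond in conditions:
        ref = ref_spec
        if ref is None:
            ref = PreprocessSpec(
                mode="none", bin_count=cond.bin_count,
                discretization=cond.discretization, bin_width=cond.bin_width,
                normalize=cond.normalize,
            )
        ref_key = (ref.bin_count, ref.discretization, ref.bin_width, ref.normalize)
        if ref_key not in references:
            logger.info("extracting reference table (%s)", _condition_name(ref))
            references[ref_key] = extract_study(manifest, ref)
        logger.info("extracting condition %s", _condition_name(cond))
        table = extract_study(manifest, cond)
        ref_table = references[ref_key]
        # regions that degenerate under a condition (e.g. a one-pixel band
        # lost to downsampling) are skipped at extraction; compare on the
        # surviving keys and say so
        key_cols = ["specimen", "region"]
        shared = pd.merge(
            table.data[key_cols], ref_table.data[key_cols], how="inner"
        )
        if len(shared) < max(len(table.data), len(ref_table.data)):
            lost = max(len(table.data), len(ref_table.data)) - len(shared)
            logger.warning(
                "%s: %d (specimen, region) pair(s) missing from one table; "
                "comparing the %d shared pairs",
                _condition_name(cond), lost, len(shared),
            )
            table = _subset_keys(table, shared)
            ref_table = _subset_keys(ref_table, shared)
        errors = error_matrix(table, ref_table)
        reports.append(summarize(errors, flag_threshold, _condition_name(cond)))

    comparisons = [
        compare_conditions(reports[i], reports[j])
        for i in range(len(reports))
        for j in range(i + 1, len(reports))
    ]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        delta_df = pd.DataFrame(
            {r.condition: r.delta_i for r in reports}
        )
        delta_df.to_csv(out_dir / "per_feature_delta.csv")
        pd.DataFrame(
            [
                {
                    "condition_a": c.a, "condition_b": c.b,
                    "M_a": c.M_a, "M_b": c.M_b,
                    "wins_a": c.wins_a, "wins_b": c.wins_b, "ties": c.ties,
                    "n": c.n, "t": c.t_statistic, "p": c.p_value,
                }
                for c in comparisons
            ]
        ).to_csv(out_dir / "comparisons.csv", index=False)
        pd.DataFrame(
            [
                {"condition": r.condition, "M": r.M,
                 "n_flagged": len(r.flagged),
                 "flagged": ";".join(r.flagged),
                 "excluded": ";".join(r.excluded_features)}
                for r in reports
            ]
        ).to_csv(out_dir / "summary.csv", index=False)
    return reports, comparisons
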