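"""Per-well aggregation, compound-effect statistics, dose–response fitting,
and per-cell intensity comparisons.

Compound effects follow the screening convention of unprotected pairwise
comparisons (Fisher's LSD): per compound, pooled-variance two-sided t-tests of
the non-PGCC and PGCC counts against the control wells, with no multiplicity
correction by default (Benjamini–Hochberg available by flag).  Dose–response
curves are four-parameter logistic (4PL) fits returning the IC50.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import __version__ as _version
from .classify import (
    ClassificationParams,
    GatingParams,
    auto_gates,
    classify_pgcc,
    gate_viability,
)
from .io import (
    MultiChannelField,
    read_plate,
    write_records,
    write_run_metadata,
    write_summaries,
)
from .segmentation import SegmentationParams, segment_field

CATEGORIES = (
    "kills_both",
    "kills_pgcc_only",
    "kills_non_pgcc_only",
    "induces_pgcc",
    "inactive",
)


@dataclasses.dataclass
class WellSummary:
    """Per-well class counts.  ``pgcc_fraction`` is NaN when no live cells."""

    well_id: str
    condition: str
    compound: str
    concentration: float
    replicate: int
    n_non_pgcc: int
    n_pgcc: int
    n_dead: int
    n_debris: int

    @property
    def pgcc_fraction(self) -> float:
        denom = self.n_pgcc + self.n_non_pgcc
        return self.n_pgcc / denom if denom else float("nan")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pgcc_fraction"] = self.pgcc_fraction
        return d


def summarize_well(
    records: pd.DataFrame,
    well_id: str = "well",
    condition: str = "",
    compound: str = "",
    concentration: float = 0.0,
    replicate: int = 1,
) -> WellSummary:
    """Count classified records by class.

    Every record must be fully classified: a non-debris record with
    unassigned viability, or a live record with unassigned ploidy, indicates
    pipeline misuse and raises.
    """
    non_debris = records[records["ploidy_class"] != "debris"]
    if (non_debris["viability"] == "unassigned").any():
        raise ValueError("unclassified records: run viability gating first")
    live = non_debris[non_debris["viability"] == "live"]
    if (live["ploidy_class"] == "unassigned").any():
        raise ValueError("unclassified records: run PGCC classification first")
    return WellSummary(
        well_id=well_id,
        condition=condition,
        compound=compound,
        concentration=concentration,
        replicate=replicate,
        n_non_pgcc=int((records["ploidy_class"] == "non_pgcc").sum()),
        n_pgcc=int((records["ploidy_class"] == "pgcc").sum()),
        n_dead=int((non_debris["viability"] == "dead").sum()),
        n_debris=int((records["ploidy_class"] == "debris").sum()),
    )


def summaries_to_frame(summaries: Iterable[WellSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided unpaired t-test with pooled variance (the LSD contrast).

    Degenerate zero-variance groups: identical means give (0, 1), different
    means an infinite statistic with p = 0.
    """
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return float("inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def compare_conditions(
    summaries: pd.DataFrame,
    control_condition: str,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Categorize each compound by its effect on non-PGCC and PGCC counts.

    Per compound, pooled-variance two-sided t-tests vs the control wells on
    the two counts.  A change is called significant when p < alpha AND the
    treated mean moves in the stated direction.  Categories:

    - ``kills_both``: significant decrease in both counts
    - ``kills_pgcc_only``: significant decrease in PGCCs only
    - ``induces_pgcc``: significant increase in PGCCs (takes precedence over
      a simultaneous non-PGCC decrease — the docetaxel phenotype)
    - ``kills_non_pgcc_only``: significant decrease in non-PGCCs only
    - ``inactive``: otherwise

    ``bh_correct=True`` applies Benjamini–Hochberg across all compound x
    count tests before categorization.
    """
    control = summaries[summaries["condition"] == control_condition]
    if control.empty:
        raise ValueError(f"no wells with control condition {control_condition!r}")
    if len(control) < 2:
        raise ValueError("need >= 2 control replicates")
    ctrl_non = control["n_non_pgcc"].to_numpy(dtype=float)
    ctrl_pgcc = control["n_pgcc"].to_numpy(dtype=float)

    treated = summaries[summaries["condition"] != control_condition]
    rows = []
    for compound, grp in treated.groupby("compound", sort=True):
        if len(grp) < 2:
            raise ValueError(f"compound {compound!r}: need >= 2 replicates")
        non = grp["n_non_pgcc"].to_numpy(dtype=float)
        pgcc = grp["n_pgcc"].to_numpy(dtype=float)
        _, p_non = _pooled_ttest(non, ctrl_non)
        _, p_pgcc = _pooled_ttest(pgcc, ctrl_pgcc)
        rows.append(
            {
                "compound": compound,
                "mean_non_pgcc": non.mean(),
                "mean_pgcc": pgcc.mean(),
                "control_mean_non_pgcc": ctrl_non.mean(),
                "control_mean_pgcc": ctrl_pgcc.mean(),
                "p_non_pgcc": p_non,
                "p_pgcc": p_pgcc,
            }
        )
    effects = pd.DataFrame(rows)
    if effects.empty:
        effects["category"] = pd.Series(dtype=str)
        return effects

    if bh_correct:
        pvals = np.concatenate([effects["p_non_pgcc"], effects["p_pgcc"]])
        adj = _benjamini_hochberg(pvals)
        k = len(effects)
        effects["p_non_pgcc"] = adj[:k]
        effects["p_pgcc"] = adj[k:]

    categories = []
    for row in effects.itertuples():
        dec_non = row.p_non_pgcc < alpha and row.mean_non_pgcc < row.control_mean_non_pgcc
        dec_pgcc = row.p_pgcc < alpha and row.mean_pgcc < row.control_mean_pgcc
        inc_pgcc = row.p_pgcc < alpha and row.mean_pgcc > row.control_mean_pgcc
        if dec_non and dec_pgcc:
            cat = "kills_both"
        elif dec_pgcc:
            cat = "kills_pgcc_only"
        elif inc_pgcc:
            cat = "induces_pgcc"
        elif dec_non:
            cat = "kills_non_pgcc_only"
        else:
            cat = "inactive"
        categories.append(cat)
    effects["category"] = categories
    return effects


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


# ---------------------------------------------------------------------------
# Dose–response: four-parameter logistic model
# ---------------------------------------------------------------------------


def four_param_logistic(
    conc: np.ndarray, top: float, bottom: float, ic50: float, hill: float
) -> np.ndarray:
    """4PL response: ``bottom + (top - bottom) / (1 + (c / ic50)**hill)``.

    With hill > 0 the curve decreases from ``top`` (zero dose) to ``bottom``
    (saturating dose); IC50 is the concentration of half-maximal inhibition.
    """
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


@dataclasses.dataclass
class DoseResponseResult:
    """Fitted 4PL parameters with fit diagnostics."""

    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    n_obs: int
    concentrations: np.ndarray = dataclasses.field(repr=False, default=None)
    responses: np.ndarray = dataclasses.field(repr=False, default=None)

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return four_param_logistic(conc, self.top, self.bottom, self.ic50, self.hill)

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 41,
            f"n observations : {self.n_obs}",
            f"converged      : {self.converged}",
            f"IC50           : {self.ic50:.6g}",
            f"Hill slope     : {self.hill:.4g}",
            f"top (0 dose)   : {self.top:.4g}",
            f"bottom (sat.)  : {self.bottom:.4g}",
            f"residual SS    : {self.rss:.4g}",
        ]
        return "\n".join(lines)


class DoseResponse:
    """4PL dose–response model, statsmodels-style.

    Parameters
    ----------
    concentrations : positive molar (or any consistent unit) doses.
    responses : viable counts normalized to control, >= 0.

    ``DoseResponse(c, r).fit()`` returns a :class:`DoseResponseResult`.
    The fit is least squares on log10-concentration with multi-start
    initialization over Hill slopes and IC50 locations.  ``converged`` is
    False when the optimizer fails or the IC50 lands outside the tested
    range by more than a factor of 100.
    """

    def __init__(self, concentrations: Sequence[float], responses: Sequence[float]):
        conc = np.asarray(concentrations, dtype=float)
        resp = np.asarray(responses, dtype=float)
        if conc.shape != resp.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive (log scale fit)")
        if np.any(resp < 0):
            raise ValueError("responses must be non-negative")
        if len(np.unique(conc)) < 4:
            raise ValueError("need >= 4 distinct concentrations for a 4PL fit")
        self.conc = conc
        self.resp = resp

    def fit(self) -> DoseResponseResult:
        conc, resp = self.conc, self.resp
        if np.ptp(resp) == 0:
            return DoseResponseResult(
                ic50=float("nan"), hill=float("nan"),
                top=float(resp[0]), bottom=float(resp[0]),
                rss=0.0, converged=False, n_obs=len(resp),
                concentrations=conc, responses=resp,
            )
        logc = np.log10(conc)

        def residuals(theta):
            top, bottom, log_ic50, hill = theta
            with np.errstate(over="ignore"):
                pred = bottom + (top - bottom) / (
                    1.0 + 10.0 ** np.clip(hill * (logc - log_ic50), -300, 300)
                )
            return pred - resp

        top0 = float(resp[np.argmin(logc)])
        bot0 = float(resp[np.argmax(logc)])
        best = None
        for hill0 in (0.5, 1.0, 2.0, 4.0):
            for q in (0.25, 0.5, 0.75):
                log_ic50_0 = float(np.quantile(logc, q))
                try:
                    sol = optimize.least_squares(
                        residuals,
                        x0=[top0, bot0, log_ic50_0, hill0],
                        method="lm" if len(resp) >= 4 else "trf",
                        max_nfev=10000,
                    )
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
        if best is None:
            return DoseResponseResult(
                ic50=float("nan"), hill=float("nan"), top=float("nan"),
                bottom=float("nan"), rss=float("nan"), converged=False,
                n_obs=len(resp), concentrations=conc, responses=resp,
            )
        top, bottom, log_ic50, hill = best.x
        if bottom > top:
            # the 4PL is invariant under (top, bottom, hill) -> (bottom, top, -hill)
            top, bottom, hill = bottom, top, -hill
        ic50 = 10.0**log_ic50
        in_range = conc.min() / 100.0 <= ic50 <= conc.max() * 100.0
        converged = bool(best.success and np.isfinite(ic50) and in_range)
        return DoseResponseResult(
            ic50=float(ic50), hill=float(hill), top=float(top), bottom=float(bottom),
            rss=float(2 * best.cost), converged=converged, n_obs=len(resp),
            concentrations=conc, responses=resp,
        )


def fit_dose_response(
    concentrations: Sequence[float], responses: Sequence[float]
) -> DoseResponseResult:
    """Convenience wrapper: ``DoseResponse(c, r).fit()``."""
    return DoseResponse(concentrations, responses).fit()


# ---------------------------------------------------------------------------
# Per-cell intensity comparison (e.g. ROS in PGCC vs non-PGCC)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class IntensityComparison:
    channel: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    pvalue: float
    median_a: float
    median_b: float
    quartiles_a: tuple[float, float]
    quartiles_b: tuple[float, float]
    median_fold: float
    method: str


def compare_intensity(
    records: pd.DataFrame,
    channel: str = "ros",
    group_a: str = "pgcc",
    group_b: str = "non_pgcc",
    method: str = "welch",
) -> IntensityComparison:
    """Compare per-cell stain intensity between two ploidy classes.

    Default: two-sided Welch t-test on log10(intensity + 1); ``student``
    (pooled variance) and ``mannwhitney`` are selectable.  Raw-unit medians
    and quartiles are returned for violin-style reporting, along with the
    median fold change a/b.
    """
    col = f"mean_{channel}"
    if col not in records.columns or records[col].isna().all():
        raise ValueError(f"channel {channel!r} not present in records")
    a = records.loc[records["ploidy_class"] == group_a, col].dropna().to_numpy(float)
    b = records.loc[records["ploidy_class"] == group_b, col].dropna().to_numpy(float)
    for name, grp in ((group_a, a), (group_b, b)):
        if len(grp) == 0:
            raise ValueError(f"group {name!r} is empty")
    la, lb = np.log10(a + 1.0), np.log10(b + 1.0)
    if method == "welch":
        res = stats.ttest_ind(la, lb, equal_var=False)
    elif method == "student":
        res = stats.ttest_ind(la, lb, equal_var=True)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError("method must be 'welch', 'student' or 'mannwhitney'")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return IntensityComparison(
        channel=channel, group_a=group_a, group_b=group_b,
        n_a=len(a), n_b=len(b),
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        median_a=med_a, median_b=med_b,
        quartiles_a=(float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        quartiles_b=(float(np.percentile(b, 25)), float(np.percentile(b, 75))),
        median_fold=med_a / med_b if med_b else float("inf"),
        method=method,
    )


# ---------------------------------------------------------------------------
# End-to-end plate processing
# ---------------------------------------------------------------------------


def analyze_field(
    field: MultiChannelField,
    seg_params: Optional[SegmentationParams] = None,
    gates: Optional[GatingParams] = None,
    class_params: Optional[ClassificationParams] = None,
    nuclear_channel: str = "nuclei",
    assume_live: bool = False,
) -> pd.DataFrame:
    """Segment, gate, and classify one field; returns the classified records.

    With ``gates=None`` thresholds are derived per field by Otsu on log
    intensities (auto gating).  ``assume_live=True`` skips viability gating
    (RFP time-lapse data).
    """
    records, _ = segment_field(field, seg_params, nuclear_channel=nuclear_channel)
    if not assume_live:
        if gates is None:
            gates = auto_gates(records)
        records = gate_viability(records, gates)
    records = classify_pgcc(
        records,
        class_params,
        magnification=field.magnification,
        pixel_size_um=field.pixel_size_um,
        assume_live=assume_live,
    )
    return records


def process_plate(
    layout_path: str | Path,
    image_root: str | Path,
    out_dir: str | Path,
    seg_params: Optional[SegmentationParams] = None,
    gates: Optional[GatingParams] = None,
    class_params: Optional[ClassificationParams] = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
    seed: Optional[int] = None,
) -> dict[str, Path]:
    """Run the full screening pipeline over a plate and write outputs.

    For every well: segmentation -> debris exclusion -> viability gating ->
    PGCC classification -> summary; then per-compound effect categorization
    vs the layout's control condition.  When no fixed gates are given, auto
    gates are derived once from the pooled records of the whole plate, so
    small wells gate consistently.  Everything is computed in memory first
    and written at the end, so a failing well leaves no partial outputs.
    Re-running on identical inputs is byte-identical.

    Returns the paths of the written files (records.csv, summaries.csv,
    effects.csv, run_metadata.json).
    """
    from .io import read_layout

    layout = read_layout(layout_path)
    segmented: list[tuple[str, object, pd.DataFrame]] = []
    for well_id, info, field in read_plate(layout_path, image_root):
        try:
            records, _ = segment_field(field, seg_params)
        except Exception as exc:
            raise RuntimeError(f"well {well_id}: {exc}") from exc
        segmented.append((well_id, info, records))

    if gates is None:
        pooled = pd.concat([r for _, _, r in segmented], ignore_index=True)
        resolved_gates = auto_gates(pooled)
    else:
        resolved_gates = gates

    all_records: list[pd.DataFrame] = []
    summaries: list[WellSummary] = []
    for well_id, info, records in segmented:
        try:
            records = gate_viability(records, resolved_gates)
            records = classify_pgcc(
                records,
                class_params,
                magnification=layout.magnification,
                pixel_size_um=layout.pixel_size_um,
            )
        except Exception as exc:
            raise RuntimeError(f"well {well_id}: {exc}") from exc
        all_records.append(records)
        summaries.append(
            summarize_well(
                records,
                well_id=well_id,
                condition=info.condition,
                compound=info.compound,
                concentration=info.concentration,
                replicate=info.replicate,
            )
        )
    records_df = (
        pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame()
    )
    summary_df = summaries_to_frame(summaries)
    effects_df = compare_conditions(
        summary_df, layout.control_condition, alpha=alpha, bh_correct=bh_correct
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "summaries": out / "summaries.csv",
        "effects": out / "effects.csv",
        "metadata": out / "run_metadata.json",
    }
    write_records(records_df, paths["records"])
    write_summaries(summary_df, paths["summaries"])
    effects_df.to_csv(paths["effects"], index=False)
    sp = seg_params or SegmentationParams.for_magnification(layout.magnification)
    cp = class_params or ClassificationParams()
    write_run_metadata(
        {
            "software": "pgccscope",
            "version": _version,
            "layout": str(layout_path),
            "image_root": str(image_root),
            "segmentation_params": dataclasses.asdict(sp),
            "classification_params": dataclasses.asdict(cp),
            "gates": dataclasses.asdict(gates) if gates else "auto (pooled plate Otsu)",
            "alpha": alpha,
            "bh_correct": bh_correct,
            "seed": seed,
        },
        paths["metadata"],
    )
    return paths
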