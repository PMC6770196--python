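"""Prediction-vs-experiment concordance statistics.

The experimental readout is an apparent association strength
(Ka_app) between a PTS1-bearing reporter and the PEX5 TPR domain,
measured for the wild-type and the mutant C-terminus.  The summary
quantity is the decadic log ratio

    log10(Ka_app_WT / Ka_app_MT)

positive when the mutant binds more weakly (loss of signal), negative
when it binds more strongly (gain).  Two predictors are compared with
it: a structure-based binding-energy change (ddG_bind, kcal/mol;
positive = weakened binding, significant outside a +/-0.5 kcal/mol
band) and the matrix score difference (MT - WT).  Pearson correlation
carries a two-sided p-value from the t transform and a 95% confidence
interval from the Fisher z transform.
"""
from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .errors import CorrelationError, Pts1ScanError

LOSS = "loss"
GAIN = "gain"
NO_CHANGE = "no_change"
OUTCOMES = (LOSS, GAIN, NO_CHANGE)

FOLDX_SIGNIFICANCE_KCAL = 0.5


@dataclass(frozen=True)
class AffinityRecord:
    """One wild-type/mutant affinity measurement with predictor values.

    Ka values are on the printed 1e-6 scale (dimensionless fitted
    units); ratios are scale-invariant so no conversion is ever
    needed.  ``ka_wt``/``ka_mt`` are ``None`` when the fit was not
    analyzable — they are flagged, never zero-filled.
    """

    gene: str
    wt_tri: str
    mt_tri: str
    ka_wt: Optional[float]
    ka_mt: Optional[float]
    ddg_bind: Optional[float]
    score_difference: Optional[float]
    experimental_outcome: str
    log_ratio_printed: Optional[float] = None

    def __post_init__(self):
        for v in (self.ka_wt, self.ka_mt):
            if v is not None and v <= 0:
                raise Pts1ScanError(
                    f"{self.gene} {self.wt_tri}>{self.mt_tri}: "
                    f"Ka values must be strictly positive, got {v}"
                )
        if self.experimental_outcome not in OUTCOMES:
            raise Pts1ScanError(
                f"unknown experimental outcome {self.experimental_outcome!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.gene}-{self.mt_tri}"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


def log_ka_ratio(ka_wt: float, ka_mt: float) -> float:
    """log10 of the wild-type over mutant apparent affinity.

    Positive means the mutant binds PEX5 more weakly than the wild
    type; negative means more strongly.  Non-positive inputs (e.g.
    fits that were not analyzable) are a domain error.
    """
    if ka_wt is None or ka_mt is None or ka_wt <= 0 or ka_mt <= 0:
        raise Pts1ScanError(
            f"log_ka_ratio requires strictly positive affinities, "
            f"got ({ka_wt}, {ka_mt})"
        )
    return math.log10(ka_wt / ka_mt)


def pearson_with_ci(
    xs: Sequence[float], ys: Sequence[float], ci_level: float = 0.95
) -> CorrelationResult:
    """Pearson r with two-sided p (t transform, n-2 df) and Fisher-z CI."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("inputs must be equal-length 1-d sequences")
    n = len(x)
    if n < 3:
        raise CorrelationError(f"need at least 3 points, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise CorrelationError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise CorrelationError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    # Fisher z interval; degenerate |r| == 1 collapses to a point.
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3)
        zcrit = sps.norm.ppf(0.5 + ci_level / 2.0)
        lo, hi = math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
    return CorrelationResult(
        r=r, p_value=float(res.pvalue), ci_low=lo, ci_high=hi, n=n
    )


def foldx_predicted_label(ddg_bind: float, significance: float = FOLDX_SIGNIFICANCE_KCAL) -> str:
    """Three-way call from a binding-energy change.

    Changes within the +/-``significance`` band are not significant
    and predict no localisation change.
    """
    if ddg_bind > significance:
        return LOSS
    if ddg_bind < -significance:
        return GAIN
    return NO_CHANGE


def foldx_concordance(
    records: Iterable[AffinityRecord],
    significance: float = FOLDX_SIGNIFICANCE_KCAL,
) -> Tuple[int, List[Tuple[str, str, str, bool]]]:
    """Count energy-change predictions that match the observed outcome.

    Returns ``(count_correct, verdicts)`` where each verdict is
    ``(label, predicted, observed, correct)``.  Records without a
    ddG value are skipped with a warning, reducing n.
    """
    verdicts: List[Tuple[str, str, str, bool]] = []
    correct = 0
    for rec in records:
        if rec.ddg_bind is None:
            warnings.warn(f"{rec.label}: missing ddG_bind, skipped", stacklevel=2)
            continue
        predicted = foldx_predicted_label(rec.ddg_bind, significance)
        ok = predicted == rec.experimental_outcome
        correct += ok
        verdicts.append((rec.label, predicted, rec.experimental_outcome, ok))
    return correct, verdicts


_CATEGORY_RANK = {"Not targeted": 0, "Twilight zone": 1, "Targeted": 2}


def predictor_concordance(
    category_changes: Iterable[Tuple[str, str, str, str]],
) -> Tuple[int, List[Tuple[str, str, str, bool]]]:
    """Concordance of categorical predictor output with observed outcomes.

    ``category_changes`` holds ``(label, wt_category, mt_category,
    experimental_outcome)`` tuples; categories are externally supplied
    predictor output (e.g. from published runs), never recomputed from
    the bundled example matrix.  The predicted direction is *gain*
    when the category rank rises, *loss* when it falls, *no_change*
    when it is unchanged; a verdict is correct iff the direction
    matches the experimental outcome.  Rows with an unknown category
    are skipped with a warning.
    """
    verdicts: List[Tuple[str, str, str, bool]] = []
    correct = 0
    for label, wt_cat, mt_cat, outcome in category_changes:
        if wt_cat not in _CATEGORY_RANK or mt_cat not in _CATEGORY_RANK:
            warnings.warn(f"{label}: unknown category, skipped", stacklevel=2)
            continue
        delta = _CATEGORY_RANK[mt_cat] - _CATEGORY_RANK[wt_cat]
        predicted = GAIN if delta > 0 else LOSS if delta < 0 else NO_CHANGE
        ok = predicted == outcome
        correct += ok
        verdicts.append((label, predicted, outcome, ok))
    return correct, verdicts


def affinity_correlations(
    records: Sequence[AffinityRecord],
) -> Dict[str, CorrelationResult]:
    """The two planned correlations against the experimental log ratio.

    Log ratios are recomputed from the Ka columns; records lacking a
    predictor value or an analyzable fit are dropped pairwise.
    """
    out: Dict[str, CorrelationResult] = {}
    for name, attr in (("ddg_bind", "ddg_bind"), ("score_difference", "score_difference")):
        xs, ys = [], []
        for rec in records:
            pred = getattr(rec, attr)
            if pred is None or rec.ka_wt is None or rec.ka_mt is None:
                continue
            xs.append(pred)
            ys.append(log_ka_ratio(rec.ka_wt, rec.ka_mt))
        out[name] = pearson_with_ci(xs, ys)
    return out


# ---------------------------------------------------------------------------
# Readers / writers / fixture


def read_affinity_tsv(path: Union[str, Path]) -> List[AffinityRecord]:
    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                AffinityRecord(
                    gene=row["gene"],
                    wt_tri=row["wt_tri"],
                    mt_tri=row["mt_tri"],
                    ka_wt=_opt_float(row.get("ka_wt")),
                    ka_mt=_opt_float(row.get("ka_mt")),
                    ddg_bind=_opt_float(row.get("ddg_bind")),
                    score_difference=_opt_float(row.get("score_difference")),
                    experimental_outcome=row["experimental_outcome"],
                    log_ratio_printed=_opt_float(row.get("log_ratio")),
                )
            )
    return records


def write_affinity_tsv(records: Iterable[AffinityRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "gene", "wt_tri", "mt_tri", "ka_wt", "ka_mt", "log_ratio",
                "ddg_bind", "score_difference", "experimental_outcome",
            ]
        )
        for r in records:
            writer.writerow(
                [
                    r.gene, r.wt_tri, r.mt_tri,
                    _fmt(r.ka_wt), _fmt(r.ka_mt), _fmt(r.log_ratio_printed),
                    _fmt(r.ddg_bind), _fmt(r.score_difference),
                    r.experimental_outcome,
                ]
            )


def gof_category_fixture() -> List[Tuple[str, str, str, str]]:
    """Categorical predictor transitions for the five gain candidates.

    Each tuple is ``(label, wt_category, mt_category, observed
    outcome)`` — the published predictor categories for the five
    cytosolic proteins selected for de-novo PTS1 testing, paired with
    the microscopy outcome.
    """
    return [
        ("PPP4R4-SNL", "Not targeted", "Targeted", GAIN),
        ("RFLNA-AKL", "Not targeted", "Targeted", GAIN),
        ("ARHGAP1-SRL", "Not targeted", "Targeted", GAIN),
        ("HPGDS-SKL", "Not targeted", "Targeted", NO_CHANGE),
        ("GLTP-CKV", "Twilight zone", "Targeted", NO_CHANGE),
    ]


def table3_fixture() -> List[AffinityRecord]:
    """The packaged affinity table: 11 tested variants with outcomes."""
    ref = resources.files("pts1scan.data").joinpath("table3_affinity.tsv")
    with resources.as_file(ref) as path:
        return read_affinity_tsv(path)


def write_scatter_tsv(
    records: Sequence[AffinityRecord], predictor: str, path: Union[str, Path]
) -> None:
    """Scatter-plot data (x = predictor value, y = log Ka ratio)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["x", "y", "label", "group"])
        for rec in records:
            pred = getattr(rec, predictor)
            if pred is None or rec.ka_wt is None or rec.ka_mt is None:
                continue
            writer.writerow(
                [pred, log_ka_ratio(rec.ka_wt, rec.ka_mt), rec.label, rec.experimental_outcome]
            )


def _opt_float(value: Optional[str]) -> Optional[float]:
    if value is None or value.strip() in ("", "NA", "n.a", "na"):
        return None
    return float(value)


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else repr(value)
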