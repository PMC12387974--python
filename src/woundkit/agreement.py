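"""Method-agreement statistics for wound measurements.

These are the accuracy / precision / reproducibility / coefficient-of-
variation conventions used in clinical validations of automated wound
measurement against digital planimetry and probe measurements.  The
exact denominators matter and are locked by fixture tests against
published per-row values:

* accuracy vs a reference: relative error |device - reference| / device,
  accuracy% = 100 (1 - mean);
* reproducibility of a repeated pair: |m1 - m2| / min(m1, m2),
  precision% = 100 (1 - mean);
* pair CV: (|m1 - m2| / sqrt(2)) / mean(m1, m2) — the two-value sample
  standard deviation over the mean;
* depth agreement: signed relative error |mean(m) - probe| / mean(m)
  (sentinel rows contribute 0, the device having reported its +/-3 mm
  floor); precision from |m1 - m2| / min(|m1|, |m2|);
* repeated-group spread: (max - min) / min, with an all-zero group
  contributing 0; group CV: sample sd / mean.

Sample (n-1) standard deviations are used throughout.  Computation is
kept at full precision; rounding happens only at presentation.

The transcribed measurement tables ship with the package under
``woundkit/data`` and are loaded with :func:`load_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class AgreementError(ValueError):
    """Raised for undefined agreement ratios (zero denominators...)."""


@dataclass(frozen=True)
class PairedMeasurement:
    device_value: float
    reference_value: float
    sentinel: bool = False


@dataclass(frozen=True)
class RepeatedGroup:
    item: object
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError(f"group {self.item!r} needs >= 2 values")


@dataclass
class AgreementReport:
    """Per-item agreement values and their aggregates.

    `formula` identifies the per-item statistic; aggregates are the
    stated functions of the per-item column (percentages are full
    precision; round only for display).
    """

    formula: str
    per_item: pd.DataFrame
    accuracy_pct: Optional[float] = None
    precision_pct: Optional[float] = None
    mean_cv_pct: Optional[float] = None


@dataclass
class BinaryEvalTable:
    per_class: pd.DataFrame     # class, n_images, n_correct, accuracy_pct

    def accuracy_pct(self, cls: str) -> float:
        row = self.per_class[self.per_class["class"] == cls]
        if row.empty:
            raise KeyError(cls)
        return float(row["accuracy_pct"].iloc[0])


def load_table(name: str) -> pd.DataFrame:
    """Load one of the packaged measurement tables (e.g. 'table3')."""
    with resources.files("woundkit.data").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh)


def accuracy_vs_reference(pairs: Sequence[PairedMeasurement]) -> AgreementReport:
    """Accuracy of single device measurements against a reference.

    Per item: e = |device - reference| / device (the device value is the
    denominator); accuracy% = 100 (1 - mean e).
    """
    rows = []
    for i, p in enumerate(pairs):
        if p.device_value == 0:
            raise AgreementError(f"item {i + 1}: device value is zero")
        err = abs(p.device_value - p.reference_value) / p.device_value
        rows.append({"device": p.device_value, "reference": p.reference_value,
                     "abs_error": abs(p.device_value - p.reference_value),
                     "relative_error": err})
    per = pd.DataFrame(rows)
    return AgreementReport(
        formula="abs(device-reference)/device",
        per_item=per,
        accuracy_pct=100.0 * (1.0 - per["relative_error"].mean()),
    )


def paired_precision(pairs: Sequence[Tuple[float, float]]) -> AgreementReport:
    """Reproducibility of repeated device pairs.

    Per pair: r = |m1 - m2| / min(m1, m2) and cv = (|m1 - m2|/sqrt 2) /
    mean; precision% = 100 (1 - mean r); mean CV% = 100 mean cv.
    """
    rows = []
    for i, (m1, m2) in enumerate(pairs):
        if m1 <= 0 or m2 <= 0:
            raise AgreementError(f"pair {i + 1}: nonpositive measurement")
        diff = abs(m1 - m2)
        rows.append({"m1": m1, "m2": m2, "diff": diff,
                     "reproducibility": diff / min(m1, m2),
                     "cv": (diff / np.sqrt(2.0)) / ((m1 + m2) / 2.0)})
    if not rows:
        raise AgreementError("no pairs given")
    per = pd.DataFrame(rows)
    return AgreementReport(
        formula="abs(m1-m2)/min(m1,m2); cv=sd/mean",
        per_item=per,
        precision_pct=100.0 * (1.0 - per["reproducibility"].mean()),
        mean_cv_pct=100.0 * per["cv"].mean(),
    )


def depth_agreement(rows: Sequence[Tuple]) -> AgreementReport:
    """Depth agreement against the probe, honouring the +/-3 mm sentinel.

    Each row is (m1, m2, probe, sentinel).  Non-sentinel rows use the
    signed relative error s = |mean(m) - probe| / mean(m) (the sign of
    the device mean carries through) and spread p = |m1 - m2| /
    min(|m1|, |m2|); sentinel rows contribute 0 to both — the device
    correctly reported a sub-resolution depth.
    """
    recs = []
    for i, (m1, m2, probe, sentinel) in enumerate(rows):
        if sentinel:
            recs.append({"m1": np.nan, "m2": np.nan, "probe": probe,
                         "sentinel": True, "signed_rel_error": 0.0,
                         "spread": 0.0})
            continue
        mean = (m1 + m2) / 2.0
        if mean == 0:
            raise AgreementError(f"row {i + 1}: zero device mean")
        if min(abs(m1), abs(m2)) == 0:
            raise AgreementError(f"row {i + 1}: zero device measurement")
        recs.append({
            "m1": m1, "m2": m2, "probe": probe, "sentinel": False,
            "signed_rel_error": abs(mean - probe) / mean,
            "spread": abs(m1 - m2) / min(abs(m1), abs(m2)),
        })
    if not recs:
        raise AgreementError("no rows given")
    per = pd.DataFrame(recs)
    return AgreementReport(
        formula="abs(mean-probe)/mean (sentinel->0); abs(m1-m2)/min|m|",
        per_item=per,
        accuracy_pct=100.0 * (1.0 - per["signed_rel_error"].mean()),
        precision_pct=100.0 * (1.0 - per["spread"].mean()),
    )


def repeated_precision(groups: Sequence[RepeatedGroup]) -> AgreementReport:
    """Precision of >= 2 repeated measurements per item.

    Per group: g = (max - min) / min, an all-zero group contributing 0;
    precision% = 100 (1 - mean g).  A zero minimum with a nonzero
    maximum leaves the ratio undefined and raises.
    """
    rows = []
    for grp in groups:
        v = np.asarray(grp.values, dtype=float)
        if np.any(v < 0):
            raise AgreementError(f"group {grp.item!r}: negative value")
        if v.max() == 0:
            g = 0.0
        elif v.min() == 0:
            raise AgreementError(
                f"group {grp.item!r}: zero minimum with nonzero maximum")
        else:
            g = (v.max() - v.min()) / v.min()
        rows.append({"item": grp.item, "n": len(v), "min": v.min(),
                     "max": v.max(), "spread": g})
    if not rows:
        raise AgreementError("no groups given")
    per = pd.DataFrame(rows)
    return AgreementReport(
        formula="(max-min)/min per group (all-zero -> 0)",
        per_item=per,
        precision_pct=100.0 * (1.0 - per["spread"].mean()),
    )


def group_cv(groups: Sequence[RepeatedGroup]) -> float:
    """Mean coefficient of variation over repeated groups, in percent.

    Per group: sample (n-1) sd / mean, an all-zero group contributing 0.
    """
    cvs = []
    for grp in groups:
        v = np.asarray(grp.values, dtype=float)
        mean = v.mean()
        sd = v.std(ddof=1)
        if mean == 0:
            if sd > 0:
                raise AgreementError(
                    f"group {grp.item!r}: zero mean with nonzero sd")
            cvs.append(0.0)
        else:
            cvs.append(sd / mean)
    if not cvs:
        raise AgreementError("no groups given")
    return 100.0 * float(np.mean(cvs))


def fraction_agreement(ai_pct: float, plan_pct: float) -> float:
    """Agreement of two tissue percentages: min/max ratio, (0,0) -> 1."""
    if ai_pct < 0 or plan_pct < 0:
        raise AgreementError("percentages must be >= 0")
    if ai_pct == 0 and plan_pct == 0:
        return 1.0
    hi = max(ai_pct, plan_pct)
    return min(ai_pct, plan_pct) / hi


def binary_eval(predicted: Sequence[str], truth: Sequence[str],
                classes: Sequence[str] = ("other", "slough", "necrosis")
                ) -> BinaryEvalTable:
    """Per-class binary presence evaluation.

    Each image carries one true and one predicted class; per-class
    accuracy is correct / n of that true class, and the predictions
    routed to each class are tallied.
    """
    if len(predicted) != len(truth):
        raise AgreementError("prediction/truth lists differ in length")
    classes = list(classes)
    for lab in list(predicted) + list(truth):
        if lab not in classes:
            raise AgreementError(f"label {lab!r} outside class set")
    pred = np.asarray(predicted)
    tru = np.asarray(truth)
    rows = []
    for cls in classes:
        sel = tru == cls
        n = int(sel.sum())
        correct = int((pred[sel] == cls).sum())
        rows.append({"class": cls, "n_images": n, "n_correct": correct,
                     "accuracy_pct": 100.0 * correct / n if n else np.nan,
                     "n_predicted_to_class": int((pred == cls).sum())})
    return BinaryEvalTable(per_class=pd.DataFrame(rows))


def binary_eval_from_counts(table: pd.DataFrame) -> BinaryEvalTable:
    """Binary evaluation from a per-class count table
    (columns: tissue, n_images, n_correct[, n_predicted_to_class])."""
    rows = []
    for _, r in table.iterrows():
        rows.append({"class": r["tissue"], "n_images": int(r["n_images"]),
                     "n_correct": int(r["n_correct"]),
                     "accuracy_pct": 100.0 * r["n_correct"] / r["n_images"],
                     "n_predicted_to_class": int(
                         r.get("n_predicted_to_class", 0))})
    return BinaryEvalTable(per_class=pd.DataFrame(rows))


# -- convenience wrappers over the packaged tables -------------------------

def table_groups(table: pd.DataFrame, column: str) -> List[RepeatedGroup]:
    """Per-patient repeated groups from a long-format table."""
    return [RepeatedGroup(item=pid, values=tuple(sub[column]))
            for pid, sub in table.groupby("patient", sort=True)]


def evaluate_table(name: str) -> Dict[str, float]:
    """Recompute the headline agreement statistics of a packaged table.

    Returns a flat dict of percentages keyed by short names; used by the
    command-line `agree` mode and the reproduction script.
    """
    t = load_table(name)
    if name == "table2":
        rep = accuracy_vs_reference(
            [PairedMeasurement(r.device_cm2, r.reference_cm2)
             for r in t.itertuples()])
        return {"area_accuracy_pct": rep.accuracy_pct}
    if name == "table3":
        rep = paired_precision(list(zip(t.measure1_cm2, t.measure2_cm2)))
        return {"area_precision_pct": rep.precision_pct,
                "area_mean_cv_pct": rep.mean_cv_pct}
    if name == "table4":
        rep = depth_agreement(
            [(r.device1_mm, r.device2_mm, r.probe_mm, bool(r.sentinel))
             for r in t.itertuples()])
        return {"depth_accuracy_pct": rep.accuracy_pct,
                "depth_precision_pct": rep.precision_pct}
    if name == "table5":
        ev = binary_eval_from_counts(t)
        return {f"binary_{r['class']}_accuracy_pct":
                float(r["accuracy_pct"]) for _, r in ev.per_class.iterrows()}
    if name == "table6":
        out = {}
        for tiss in ("slough", "necrosis"):
            # headline means validate against the printed per-wound column
            out[f"pixel_{tiss}_agreement_pct"] = float(
                100.0 * t[f"printed_agreement_{tiss}"].mean())
        return out
    if name == "table7":
        out = {}
        for col, key in [("ai_slough_pct", "ai_slough"),
                         ("ai_necrosis_pct", "ai_necrosis"),
                         ("plan_slough_pct", "planimetry_slough"),
                         ("plan_necrosis_pct", "planimetry_necrosis")]:
            groups = table_groups(t, col)
            out[f"{key}_precision_pct"] = repeated_precision(
                groups).precision_pct
            out[f"{key}_mean_cv_pct"] = group_cv(groups)
        return out
    raise KeyError(name)
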