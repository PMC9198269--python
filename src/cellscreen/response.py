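"""Sensitive / resistant / excluded classification from IC50 or AUDRC values.

Lower response values mean greater sensitivity for both metrics.  The tertile
scheme labels the lower third sensitive and the upper third resistant and
excludes the middle; the median scheme splits at the median and excludes
exact ties.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .datastore import DrugResponseRecord
from .errors import ValidationError

SENSITIVE = "sensitive"
RESISTANT = "resistant"
EXCLUDED = "excluded"


@dataclass
class ResponseLabeling:
    """Per-cell-line response calls for one compound in one dataset."""

    dataset: str
    compound: str
    metric: str  # 'ic50' | 'audrc'
    scheme: str  # 'tertile' | 'median'
    lower_cutoff: float
    upper_cutoff: float
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lower_cutoff > self.upper_cutoff:
            raise ValidationError("lower_cutoff must not exceed upper_cutoff")

    def lines_with(self, label: str) -> list[str]:
        return sorted(cl for cl, lab in self.labels.items() if lab == label)

    @property
    def n_sensitive(self) -> int:
        return sum(1 for lab in self.labels.values() if lab == SENSITIVE)

    @property
    def n_resistant(self) -> int:
        return sum(1 for lab in self.labels.values() if lab == RESISTANT)


def _label(value: float, lower: float, upper: float) -> str:
    sens = value <= lower
    res = value >= upper
    if sens and res:  # possible only when cutoffs coincide
        return EXCLUDED
    if sens:
        return SENSITIVE
    if res:
        return RESISTANT
    return EXCLUDED


def _interpolated_tertile(sorted_values: np.ndarray, third: int) -> float:
    """Value at fractional rank third*(n-1)/3 (linear interpolation)."""
    k, r = divmod(third * (len(sorted_values) - 1), 3)
    if r == 0:
        return float(sorted_values[k])
    lo, hi = sorted_values[k], sorted_values[k + 1]
    return float(lo + (r / 3.0) * (hi - lo))


def classify_tertile(values: dict[str, float], *, dataset: str = "", compound: str = "",
                     metric: str = "audrc") -> ResponseLabeling:
    """Tertile classification: lower third sensitive, upper third resistant.

    Cutoffs are the 33.33th and 66.67th percentiles (linear interpolation
    between order statistics).  A value satisfying both cutoff conditions
    (degenerate distributions only) is excluded.
    """
    if len(values) < 6:
        raise ValidationError(f"insufficient cell lines: need >= 6, got {len(values)}")
    arr = np.sort(np.array(list(values.values()), dtype=float))
    # type-7 interpolation with exact index arithmetic: np.percentile(x, 100/3)
    # rounds the fractional rank and can miss a cutoff that lands exactly on
    # an order statistic, breaking exact negation antisymmetry
    lower = _interpolated_tertile(arr, 1)
    upper = _interpolated_tertile(arr, 2)
    labels = {cl: _label(v, lower, upper) for cl, v in values.items()}
    return ResponseLabeling(dataset, compound, metric, "tertile",
                            float(lower), float(upper), labels)


def classify_median(values: dict[str, float], *, dataset: str = "", compound: str = "",
                    metric: str = "audrc") -> ResponseLabeling:
    """Median split: below the median sensitive, above resistant, ties excluded."""
    if len(values) < 4:
        raise ValidationError(f"insufficient cell lines: need >= 4, got {len(values)}")
    med = float(np.median(list(values.values())))
    labels = {}
    for cl, v in values.items():
        if v < med:
            labels[cl] = SENSITIVE
        elif v > med:
            labels[cl] = RESISTANT
        else:
            labels[cl] = EXCLUDED
    return ResponseLabeling(dataset, compound, metric, "median", med, med, labels)


def classify(values: dict[str, float], scheme: str = "tertile", **kwargs) -> ResponseLabeling:
    if scheme == "tertile":
        return classify_tertile(values, **kwargs)
    if scheme == "median":
        return classify_median(values, **kwargs)
    raise ValidationError(f"unknown scheme {scheme!r}")


def select_metric(records: list[DrugResponseRecord],
                  preference: str = "audrc_first",
                  min_cell_lines: int = 6) -> tuple[str, dict[str, float]]:
    """Choose the response metric for one (dataset, compound) record group.

    The preferred metric is used when at least ``min_cell_lines`` cell lines
    report it, falling back to the other one otherwise.  Duplicate
    measurements for a cell line are averaged.
    """
    if preference not in ("audrc_first", "ic50_first"):
        raise ValidationError(f"unknown preference {preference!r}")
    if not records:
        raise ValidationError("no records")
    keys = {(r.dataset, r.compound) for r in records}
    if len(keys) > 1:
        raise ValidationError(f"records span multiple (dataset, compound) pairs: {sorted(keys)}")

    per_metric: dict[str, dict[str, list[float]]] = {"ic50": defaultdict(list),
                                                     "audrc": defaultdict(list)}
    for r in records:
        if r.ic50 is not None:
            per_metric["ic50"][r.cell_line].append(r.ic50)
        if r.audrc is not None:
            per_metric["audrc"][r.cell_line].append(r.audrc)

    order = ("audrc", "ic50") if preference == "audrc_first" else ("ic50", "audrc")
    for metric in order:
        if len(per_metric[metric]) >= min_cell_lines:
            values = {cl: float(np.mean(v)) for cl, v in per_metric[metric].items()}
            return metric, values
    raise ValidationError(
        f"neither metric reaches {min_cell_lines} cell lines "
        f"(ic50: {len(per_metric['ic50'])}, audrc: {len(per_metric['audrc'])})"
    )


def filter_compounds(records: list[DrugResponseRecord],
                     min_cell_lines: int = 100) -> set[str]:
    """Compounds measured in >= ``min_cell_lines`` distinct cell lines in at
    least one dataset (counts are per dataset, not pooled)."""
    lines: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in records:
        lines[(r.dataset, r.compound)].add(r.cell_line)
    return {compound for (_, compound), cls in lines.items() if len(cls) >= min_cell_lines}
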