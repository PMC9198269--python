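"""Cell-line model ranking and multi-dataset overlap accounting."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .errors import ValidationError


@dataclass(frozen=True)
class CellLineRank:
    cell_line: str
    standardized_audrc: float
    rank: int
    disease: str | None = None


@dataclass
class OverlapReport:
    """Venn-region cardinalities for 2-4 datasets plus aggregates."""

    category: str
    datasets: list[str]
    regions: dict[tuple[str, ...], int]  # exclusive membership patterns
    union_size: int
    in_at_least_two: int
    in_all: int

    @property
    def pct_at_least_two(self) -> float:
        return 100.0 * self.in_at_least_two / self.union_size if self.union_size else 0.0

    @property
    def pct_in_all(self) -> float:
        return 100.0 * self.in_all / self.union_size if self.union_size else 0.0

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "datasets": self.datasets,
            "regions": {"&".join(k): v for k, v in sorted(self.regions.items())},
            "union_size": self.union_size,
            "in_at_least_two": self.in_at_least_two,
            "in_all": self.in_all,
            "pct_at_least_two": self.pct_at_least_two,
            "pct_in_all": self.pct_in_all,
        }


def standardize_audrc(audrc: float, dose_range_width: float,
                      max_response: float = 1.0) -> float:
    """AUDRC divided by its theoretical maximum area — the mean response over
    the tested dose range, on a [0, 1] scale."""
    if dose_range_width <= 0 or max_response <= 0:
        raise ValidationError("dose_range_width and max_response must be positive")
    if audrc < 0:
        raise ValidationError(f"AUDRC must be non-negative, got {audrc}")
    ceiling = dose_range_width * max_response
    if audrc > ceiling * (1 + 1e-12):
        raise ValidationError(f"AUDRC {audrc} exceeds theoretical maximum {ceiling}")
    return min(audrc / ceiling, 1.0)


def rank_cell_lines(values: dict[str, float],
                    annotations: dict[str, str] | None = None,
                    k: int = 10) -> tuple[list[CellLineRank], list[CellLineRank], list[CellLineRank]]:
    """Rank cell lines by ascending response value.

    Returns (top-k sensitive ascending, top-k resistant descending, full
    ranking ascending).  Ties are ordered by cell-line name.
    """
    if not values:
        raise ValidationError("no cell lines to rank")
    annotations = annotations or {}
    ordered = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
    full = [CellLineRank(cl, float(v), i + 1, annotations.get(cl))
            for i, (cl, v) in enumerate(ordered)]
    if len(full) < 2 * k:
        import warnings
        warnings.warn(f"only {len(full)} cell lines for k={k}; lists may overlap")
    sensitive = full[:k]
    resistant = list(reversed(full[-k:])) if k else []
    return sensitive, resistant, full


def overlap_report(sets: dict[str, set], category: str = "items") -> OverlapReport:
    """All Venn-region cardinalities for 2-4 named sets, with 'in >= 2' and
    'in all' aggregates."""
    names = sorted(sets)
    if not 2 <= len(names) <= 4:
        raise ValidationError(f"overlap report supports 2-4 datasets, got {len(names)}")
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo)) if combo else set()
            outside = set().union(*(sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            regions[combo] = len(inside - outside)
    membership_counts = {item: sum(item in sets[n] for n in names) for item in universe}
    in_two = sum(1 for c in membership_counts.values() if c >= 2)
    in_all = sum(1 for c in membership_counts.values() if c == len(names))
    return OverlapReport(category=category, datasets=names, regions=regions,
                         union_size=len(universe), in_at_least_two=in_two, in_all=in_all)
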