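"""Synthetic multi-dataset cohorts with planted biomarker effects.

A latent per-cell-line resistance score drives everything: planted genes
shift their log-scale expression proportionally to the score, IC50 grows
exponentially with it, and viability follows a Hill curve whose area over
the log-dose range yields the AUDRC.  Ground truth is retained so recovery
can be checked exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .datastore import DrugResponseRecord, ExpressionMatrix
from .errors import ValidationError


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort.

    ``planted_genes`` holds (gene index, effect size, sign) triples; the
    effect size is in units of the within-gene log-scale standard deviation
    (``expr_log_sd``), and the sign says whether expression rises (+1) or
    falls (-1) with resistance.
    """

    n_genes: int
    n_cell_lines: int
    seed: int
    n_datasets: int = 1
    cell_line_overlap_fraction: float = 1.0
    planted_genes: list[tuple[int, float, int]] = field(default_factory=list)
    hill_slope: float = 1.0
    min_dose: float = 1e-3
    max_dose: float = 10.0
    n_doses: int = 9
    noise_sd: float = 0.1
    expr_log_sd: float = 0.5
    compound: str = "DRUG1"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cell_lines < 1:
            raise ValidationError("n_genes and n_cell_lines must be positive")
        if not 1 <= self.n_datasets <= 4:
            raise ValidationError("n_datasets must be 1-4")
        if not 0.0 <= self.cell_line_overlap_fraction <= 1.0:
            raise ValidationError("cell_line_overlap_fraction must lie in [0, 1]")
        if self.min_dose <= 0 or self.max_dose <= self.min_dose:
            raise ValidationError("doses must satisfy 0 < min_dose < max_dose")
        if self.n_doses < 2:
            raise ValidationError("need >= 2 dose points")
        if self.noise_sd < 0 or self.expr_log_sd < 0 or self.hill_slope <= 0:
            raise ValidationError("noise_sd/expr_log_sd non-negative, hill_slope positive")
        self.planted_genes = [(int(i), float(e), int(s)) for i, e, s in self.planted_genes]
        for i, _, s in self.planted_genes:
            if not 0 <= i < self.n_genes:
                raise ValidationError(f"planted gene index {i} out of range")
            if s not in (-1, 1):
                raise ValidationError(f"planted gene sign must be +-1, got {s}")

    @property
    def doses(self) -> np.ndarray:
        return np.geomspace(self.min_dose, self.max_dose, self.n_doses)

    @property
    def dose_range_width(self) -> float:
        return float(np.log10(self.max_dose / self.min_dose))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortSpec":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class CohortTruth:
    resistance_score: dict[str, float]  # latent z per cell line
    ic50: dict[str, float]              # noise-free latent IC50
    audrc: dict[str, float]             # AUDRC of the latent Hill curve
    planted_genes: list[tuple[str, float, int]]
    dose_range_width: float
    compound: str


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    expression: dict[str, ExpressionMatrix]  # per dataset, raw counts
    records: list[DrugResponseRecord]
    truth: CohortTruth


def _hill_audrc(ic50: np.ndarray, doses: np.ndarray, slope: float) -> np.ndarray:
    """Trapezoidal area of 1 / (1 + (d / ic50)^slope) over log10-dose."""
    viability = 1.0 / (1.0 + (doses[None, :] / ic50[:, None]) ** slope)
    return np.trapezoid(viability, np.log10(doses), axis=1)


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Deterministically generate a cohort from its spec.

    Cell lines are partitioned into a shared block present in every dataset
    (``cell_line_overlap_fraction`` of the cohort) plus dataset-exclusive
    blocks; expression counts and response measurements are re-drawn with
    independent noise per dataset around the shared latent state.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(len(str(spec.n_cell_lines)), 4)
    cell_lines = [f"CL{i:0{width}d}" for i in range(1, spec.n_cell_lines + 1)]
    gwidth = max(len(str(spec.n_genes)), 4)
    genes = [f"G{i:0{gwidth}d}" for i in range(1, spec.n_genes + 1)]
    datasets = [f"DS{i}" for i in range(1, spec.n_datasets + 1)]

    z = rng.standard_normal(spec.n_cell_lines)
    base_log = rng.uniform(np.log(50.0), np.log(2000.0), size=spec.n_genes)
    effect = np.zeros(spec.n_genes)
    for idx, eff, sign in spec.planted_genes:
        effect[idx] = eff * sign * spec.expr_log_sd

    # latent dose-response
    log_mid = np.log(np.sqrt(spec.min_dose * spec.max_dose))
    true_ic50 = np.exp(log_mid + z)
    true_audrc = _hill_audrc(true_ic50, spec.doses, spec.hill_slope)

    # assign cell lines to datasets
    n_shared = int(round(spec.cell_line_overlap_fraction * spec.n_cell_lines))
    membership: dict[str, list[int]] = {ds: list(range(n_shared)) for ds in datasets}
    for offset, j in enumerate(range(n_shared, spec.n_cell_lines)):
        membership[datasets[offset % spec.n_datasets]].append(j)
    for ds in datasets:
        if len(membership[ds]) < 6:
            raise ValidationError(
                f"dataset {ds} would contain {len(membership[ds])} cell lines; "
                "increase n_cell_lines or the overlap fraction"
            )

    expression: dict[str, ExpressionMatrix] = {}
    records: list[DrugResponseRecord] = []
    for ds in datasets:
        cols = membership[ds]
        log_mean = base_log[:, None] + effect[:, None] * z[None, cols]
        noise = rng.standard_normal((spec.n_genes, len(cols))) * spec.expr_log_sd
        counts = np.rint(np.exp(log_mean + noise))
        expression[ds] = ExpressionMatrix(
            genes=list(genes),
            cell_lines=[cell_lines[j] for j in cols],
            values=np.clip(counts, 0, None),
            state="raw_counts",
        )
        meas_ic50 = true_ic50[cols] * np.exp(rng.standard_normal(len(cols)) * spec.noise_sd)
        meas_audrc = _hill_audrc(meas_ic50, spec.doses, spec.hill_slope)
        for j, ic, au in zip(cols, meas_ic50, meas_audrc):
            records.append(DrugResponseRecord(ds, spec.compound, cell_lines[j],
                                              float(ic), float(au)))

    truth = CohortTruth(
        resistance_score=dict(zip(cell_lines, z.tolist())),
        ic50=dict(zip(cell_lines, true_ic50.tolist())),
        audrc=dict(zip(cell_lines, true_audrc.tolist())),
        planted_genes=[(genes[i], e, s) for i, e, s in spec.planted_genes],
        dose_range_width=spec.dose_range_width,
        compound=spec.compound,
    )
    return SyntheticCohort(spec=spec, expression=expression, records=records, truth=truth)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write expression TSVs (one per dataset), the pooled response TSV, and
    the ground-truth JSON.  Returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for ds, m in cohort.expression.items():
        p = os.path.join(out_dir, f"expression_{ds}.tsv")
        df = m.to_frame()
        df.index.name = "gene"
        df.to_csv(p, sep="\t", float_format="%.0f")
        paths[f"expression_{ds}"] = p
    rp = os.path.join(out_dir, "responses.tsv")
    with open(rp, "w", encoding="utf-8") as fh:
        fh.write("dataset\tcompound\tcell_line\tic50\taudrc\n")
        for r in cohort.records:
            ic = "" if r.ic50 is None else repr(r.ic50)
            au = "" if r.audrc is None else repr(r.audrc)
            fh.write(f"{r.dataset}\t{r.compound}\t{r.cell_line}\t{ic}\t{au}\n")
    paths["responses"] = rp
    tp = os.path.join(out_dir, "truth.json")
    truth = cohort.truth
    with open(tp, "w", encoding="utf-8") as fh:
        json.dump({
            "resistance_score": truth.resistance_score,
            "ic50": truth.ic50,
            "audrc": truth.audrc,
            "planted_genes": [{"gene": g, "effect_size": e, "sign": s}
                              for g, e, s in truth.planted_genes],
            "dose_range_width": truth.dose_range_width,
            "compound": truth.compound,
        }, fh, indent=2, sort_keys=True)
    paths["truth"] = tp
    return paths
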