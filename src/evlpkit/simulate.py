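"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emits the exact tabular/FASTA dialect its analysis
counterpart reads, and is the analytic inverse of that counterpart in the
noiseless limit: a standard series generated from a known slope/intercept
is refitted exactly; a prep generated from a known copies/μL titer
quantifies back to that titer; a logistic time course reproduces its
closed-form plateau; a planted peptide is found by the scanners at the
planted coordinates.  Noise models are Gaussian on Ct (default σ 0.15
cycles) and multiplicative log-normal on RLU (default CV 10%).  All
randomness flows through one recorded seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qpcr import DilutionSeries, WorkflowParams, copies_per_ul_prep, ng_to_copies
from .sequence_tools import _CODON_TO_AA, _revcomp

__all__ = [
    "SimTruth",
    "Condition",
    "default_time_grid",
    "gen_standard_series",
    "gen_prep_samples",
    "gen_timecourses",
    "gen_plasmid_with_motif",
]

_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TO_AA.items():
    if _aa != "*":
        _BACK_TABLE.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth shared by the generators.

    The qPCR side is defined by the true prep titer, the true curve
    (slope from ``efficiency``, intercept ``curve_intercept``) and the
    workflow volumes; the kinetics side by a logistic
    L/(1+exp(-k(t-t50))) riding on a constant per-well baseline.
    """

    copies_per_ul_prep: float = 6e6
    efficiency: float = 0.95  # fractional; within the assay's ~0.92-0.98
    curve_intercept: float = 1.0  # log10 ng at Ct 0
    ct_noise_sd: float = 0.15  # cycles
    params: WorkflowParams = field(default_factory=WorkflowParams)
    no_rt_fold_range: tuple[float, float] = (20.0, 26.0)
    # live-cell kinetics
    baseline_rlu: float = 100.0
    plateau_rlu_per_ul: float = 1e5
    rate_per_h: float = 3.0
    midpoint_h: float = 1.0
    saturation_dose_ul: float = 5.0
    inhibitor_fold: float = 4.0
    rlu_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")

    @property
    def slope(self) -> float:
        """Slope of log10(ng) on Ct implied by the true efficiency."""
        return -np.log10(1.0 + self.efficiency)

    def true_ct(self, ng: float) -> float:
        return (np.log10(ng) - self.curve_intercept) / self.slope


@dataclass(frozen=True)
class Condition:
    """One live-cell condition: a dose, optionally an inhibitor."""

    name: str
    dose_ul: float = 1.0
    inhibitor_fold: float = 1.0
    n_wells: int = 3


def default_time_grid() -> np.ndarray:
    """-1 h baseline, 5-min sampling for the first hour, 30-min to 5 h."""
    first = np.arange(0.0, 1.0 + 1e-9, 5.0 / 60.0)
    later = np.arange(1.5, 5.0 + 1e-9, 0.5)
    return np.concatenate([[-1.0], first, later])


def gen_standard_series(
    truth: SimTruth,
    n_points: int = 7,
    fold_step: float = 10.0,
    anchor_conc_ng: float = 1e-2,
    n_replicates: int = 3,
    target: str = "scaffold",
) -> tuple[pd.DataFrame, DilutionSeries]:
    """Triplicate standard rows for a fold-step dilution ladder.

    Ct = (log10(conc) - b)/m plus Gaussian noise.  Returns the plate rows
    and the matching :class:`DilutionSeries` (anchored at the top point,
    emulating a ladder quantified once and inferred downward).
    """
    if n_points < 3:
        raise ValueError("need >= 3 dilution points")
    rng = np.random.default_rng(truth.seed)
    labels = tuple(f"d{i}" for i in range(n_points))
    series = DilutionSeries(
        anchor_conc=anchor_conc_ng, anchor_label=labels[0],
        labels=labels, fold_step=fold_step,
    )
    rows = []
    for label, conc in series.concentrations().items():
        ct0 = truth.true_ct(conc)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": f"std_{label}",
                    "target": target,
                    "role": "standard",
                    "dilution": label,
                    "replicate": rep,
                    "ct": float(ct0 + rng.normal(0.0, truth.ct_noise_sd)),
                }
            )
    return pd.DataFrame(rows), series


def gen_prep_samples(
    truth: SimTruth,
    n_preps: int = 1,
    n_replicates: int = 3,
    target: str = "scaffold",
    include_no_rt: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test-sample rows implied by the true prep titer, plus a truth table.

    The true titer is pushed backwards through the scaling chain to an
    expected ng per reaction, then to a true Ct on the true curve; noisy
    triplicates are emitted, with an optional no-RT row 20-26-fold lower
    (residual plasmid signal).  Returns (plate rows, truth table).
    """
    rng = np.random.default_rng(truth.seed + 1)
    chain = copies_per_ul_prep(1.0, truth.params)  # prep copies per reaction copy
    ng_per_copy = 1.0 / ng_to_copies(1.0, truth.params)
    rows, truths = [], []
    for p in range(1, n_preps + 1):
        name = f"prep{p}"
        copies_rxn = truth.copies_per_ul_prep / chain
        ct0 = truth.true_ct(copies_rxn * ng_per_copy)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": name, "target": target, "role": "test",
                    "dilution": "", "replicate": rep,
                    "ct": float(ct0 + rng.normal(0.0, truth.ct_noise_sd)),
                }
            )
        no_rt_fold = float(rng.uniform(*truth.no_rt_fold_range))
        if include_no_rt:
            ct_nort = truth.true_ct(copies_rxn * ng_per_copy / no_rt_fold)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": name, "target": target, "role": "noRT",
                        "dilution": "", "replicate": rep,
                        "ct": float(ct_nort + rng.normal(0.0, truth.ct_noise_sd)),
                    }
                )
        truths.append(
            {
                "sample": name,
                "true_copies_per_ul_prep": truth.copies_per_ul_prep,
                "no_rt_fold": no_rt_fold,
                "seed": truth.seed,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truths)


def gen_timecourses(
    truth: SimTruth,
    conditions: list[Condition],
    times_h: np.ndarray | None = None,
    baseline_time_h: float = -1.0,
) -> pd.DataFrame:
    """Long-format live-cell luminescence rows for a set of conditions.

    RLU(t) = scale_w × [baseline + L_eff/(1+exp(-k(t-t50)))] with log-normal
    measurement noise; L_eff scales with dose up to the saturation cap and
    is divided by the condition's inhibitor fold.  The baseline row at
    ``baseline_time_h`` carries only scale_w × baseline (pre-treatment).
    """
    times = default_time_grid() if times_h is None else np.asarray(times_h, float)
    rng = np.random.default_rng(truth.seed + 2)
    sigma = np.sqrt(np.log1p(truth.rlu_cv**2)) if truth.rlu_cv > 0 else 0.0
    rows = []
    for cond in conditions:
        eff_dose = min(cond.dose_ul, truth.saturation_dose_ul)
        plateau = truth.plateau_rlu_per_ul * eff_dose / cond.inhibitor_fold
        for w in range(1, cond.n_wells + 1):
            scale = float(rng.uniform(0.5, 2.0))  # well-to-well factor
            for t in times:
                if t <= baseline_time_h:
                    signal = truth.baseline_rlu
                else:
                    signal = truth.baseline_rlu + plateau / (
                        1.0 + np.exp(-truth.rate_per_h * (t - truth.midpoint_h))
                    )
                noise = np.exp(rng.normal(0.0, sigma) - sigma**2 / 2) if sigma else 1.0
                rows.append(
                    {
                        "well": f"{cond.name}_w{w}",
                        "condition": cond.name,
                        "time_h": round(float(t), 6),
                        "rlu": float(scale * signal * noise),
                    }
                )
    return pd.DataFrame(rows)


def gen_plasmid_with_motif(
    length_nt: int,
    peptide: str,
    frame: int,
    offset: int,
    n_mutations: int = 0,
    seed: int = 0,
    source_id: str = "synthetic_plasmid",
) -> tuple[SeqRecord, dict]:
    """Random DNA with a (possibly mutated) peptide planted in one frame.

    The peptide is reverse-translated with random codon choices and placed
    so that translation of ``frame`` yields it at peptide offset
    ``offset``; ``n_mutations`` residues are substituted first.  Returns
    the record and an annotation with the expected hit coordinates.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError("frame must be one of +-1,+-2,+-3")
    if length_nt < 3 * len(peptide) + 6:
        raise ValueError("sequence too short for the planted peptide")
    if not 0 <= n_mutations <= len(peptide):
        raise ValueError("n_mutations out of range")
    rng = np.random.default_rng(seed)

    planted = list(peptide)
    positions = rng.choice(len(peptide), size=n_mutations, replace=False)
    for pos in positions:
        choices = [aa for aa in _BACK_TABLE if aa != planted[pos]]
        planted[pos] = str(rng.choice(sorted(choices)))
    coding = "".join(str(rng.choice(sorted(_BACK_TABLE[aa]))) for aa in planted)

    shift = abs(frame) - 1
    strand_pos = shift + 3 * offset  # on the reading strand
    if frame > 0:
        start = strand_pos
    else:
        start = length_nt - strand_pos - len(coding)
    if start < 0 or start + len(coding) > length_nt:
        raise ValueError("offset/frame incompatible with sequence length")

    background = rng.choice(list("ACGT"), size=length_nt)
    seq = list("".join(background))
    insert = coding if frame > 0 else _revcomp(coding)
    seq[start : start + len(coding)] = insert
    record = SeqRecord(Seq("".join(seq)), id=source_id, description="synthetic")
    annotation = {
        "source_id": source_id,
        "peptide": "".join(planted),
        "query": peptide,
        "frame": frame,
        "offset": offset,
        "nt_start": start,
        "n_mutations": n_mutations,
        "seed": seed,
    }
    return record, annotation
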