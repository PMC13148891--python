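"""Absolute sgRNA copy-number quantification from qPCR data.

The assay quantifies sgRNA copies per microlitre of an eVLP preparation:
a 10-fold serial dilution of a synthetic standard oligonucleotide gives a
standard curve (log10 amount vs Ct); test-sample Cts are interpolated to
nanograms, converted to molecule counts via Avogadro's number and the
amplicon's single-stranded mass, and scaled back through the wet-lab chain
(cDNA dilution and reaction volume, RNA input and elution volumes, prep
volume extracted) to a per-μL titer of the original preparation.

Replicate QC follows the plate convention that a triplicate whose Ct
standard deviation exceeds 0.5 cycles has its worst point discarded once;
groups that still fail are excluded from curves and quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AVOGADRO",
    "SSDNA_NT_MASS_G_PER_MOL",
    "NG_PER_G",
    "CtReplicateGroup",
    "DilutionSeries",
    "StandardCurve",
    "WorkflowParams",
    "PrepTiter",
    "GenomeNormalizedLoad",
    "read_plate",
    "filter_replicates",
    "fit_standard_curve",
    "ct_to_ng",
    "ng_to_copies",
    "copies_per_ul_prep",
    "plasmid_load_per_genome",
    "quantify_plate",
]

AVOGADRO = 6.022e23  # molecules/mol
SSDNA_NT_MASS_G_PER_MOL = 330.0  # average mass of one nt of ssDNA
NG_PER_G = 1e9

#: Canonical long-format plate columns.
PLATE_COLUMNS = ["sample", "target", "role", "dilution", "replicate", "ct"]


@dataclass
class CtReplicateGroup:
    """Replicate Ct values for one (sample, target, role, dilution) cell.

    ``ct_values`` holds the numeric Cts; non-detects are recorded in
    ``n_nd`` rather than imputed.
    """

    sample: str
    target: str
    role: str  # standard | test | noRT | NTC
    ct_values: list[float]
    dilution: str = ""
    n_nd: int = 0

    def __post_init__(self) -> None:
        if any(ct <= 0 for ct in self.ct_values):
            raise ValueError("Ct values must be positive")


@dataclass(frozen=True)
class DilutionSeries:
    """A fold-step dilution ladder anchored at one measured concentration.

    ``anchor_conc`` is the measured amount (ng) at ``anchor_label``;
    every subsequent step is inferred by dividing by ``fold_step``.
    """

    anchor_conc: float
    anchor_label: str
    labels: tuple[str, ...]
    fold_step: float = 10.0

    def concentrations(self) -> dict[str, float]:
        if self.anchor_label not in self.labels:
            raise ValueError("anchor label not among the series labels")
        i0 = self.labels.index(self.anchor_label)
        return {
            lab: self.anchor_conc / self.fold_step ** (i - i0)
            for i, lab in enumerate(self.labels)
        }


@dataclass(frozen=True)
class StandardCurve:
    """Fitted y = m·Ct + b with y = log10(amount in ng).

    ``efficiency`` is the fractional per-cycle amplification gain,
    10^(−m) − 1 (1.0 means perfect doubling).
    """

    m: float
    b: float
    r_squared: float
    n_points: int
    ct_range: tuple[float, float]
    flags: tuple[str, ...] = ()

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-self.m) - 1.0


@dataclass(frozen=True)
class WorkflowParams:
    """Constants and volumes of the copies-per-μL-of-prep scaling chain."""

    amplicon_length_bp: float = 69.0
    cdna_dilution_factor: float = 100.0  # 10 or 100
    cdna_reaction_volume_ul: float = 20.0
    rna_volume_ul: float = 4.0  # sample-specific (normalization to 100 ng)
    elution_volume_ul: float = 30.0
    prep_volume_ul: float = 5.0
    avogadro: float = AVOGADRO
    nt_mass_g_per_mol: float = SSDNA_NT_MASS_G_PER_MOL
    ng_per_g: float = NG_PER_G

    def __post_init__(self) -> None:
        for name in (
            "amplicon_length_bp",
            "cdna_reaction_volume_ul",
            "rna_volume_ul",
            "elution_volume_ul",
            "prep_volume_ul",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cdna_dilution_factor < 1:
            raise ValueError("cdna_dilution_factor must be >= 1")


@dataclass(frozen=True)
class PrepTiter:
    sample: str
    copies_per_ul_reaction: float
    copies_per_ul_prep: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GenomeNormalizedLoad:
    sample: str
    copies_per_100_genomes: float
    control_gene: str
    control_copies_per_genome: float
    flags: tuple[str, ...] = ()


def read_plate(path) -> pd.DataFrame:
    """Read a long-format plate CSV (``sample,target,role,dilution,replicate,ct``).

    ``ct`` may be "ND" for a non-detect; it is kept as NaN.
    """
    df = pd.read_csv(path, dtype={"dilution": str})
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate file missing columns: {sorted(missing)}")
    df["ct"] = pd.to_numeric(
        df["ct"].replace({"ND": np.nan, "nd": np.nan}), errors="raise"
    )
    return df


def groups_from_plate(df: pd.DataFrame) -> list[CtReplicateGroup]:
    out = []
    for (sample, target, role, dilution), sub in df.groupby(
        ["sample", "target", "role", "dilution"], dropna=False, sort=False
    ):
        cts = sub["ct"].dropna().tolist()
        out.append(
            CtReplicateGroup(
                sample=str(sample),
                target=str(target),
                role=str(role),
                dilution="" if pd.isna(dilution) else str(dilution),
                ct_values=cts,
                n_nd=int(sub["ct"].isna().sum()),
            )
        )
    return out


def filter_replicates(
    group: CtReplicateGroup, sd_threshold: float = 0.5
) -> tuple[list[float], list[str]]:
    """Apply the 0.5-cycle replicate-SD rule.

    If the sample SD of the Cts exceeds ``sd_threshold``, the single value
    farthest from the median is removed and the group re-tested; at most
    one value is removed.  A group that still fails is flagged ``invalid``
    and must not enter curves or quantification.  Returns (kept Cts, flags).
    """
    flags: list[str] = []
    cts = list(group.ct_values)
    if group.n_nd:
        flags.append(f"nd:{group.n_nd}")
    if not cts:
        flags.append("non_quantifiable")
        return [], flags
    if len(cts) == 1:
        flags.append("singleton")
        return cts, flags
    if float(np.std(cts, ddof=1)) <= sd_threshold:
        return cts, flags
    med = float(np.median(cts))
    # tie-break toward the highest Ct (weakest signal)
    worst = max(range(len(cts)), key=lambda i: (abs(cts[i] - med), cts[i]))
    removed = cts.pop(worst)
    flags.append(f"discarded_ct:{removed:g}")
    if len(cts) < 2 or float(np.std(cts, ddof=1)) > sd_threshold:
        flags.append("invalid")
    return cts, flags


def fit_standard_curve(
    standards: list[CtReplicateGroup],
    series: DilutionSeries,
    sd_threshold: float = 0.5,
) -> StandardCurve:
    """OLS of log10(ng) on mean Ct across the dilution ladder.

    Each dilution point contributes its replicate-filtered mean Ct; groups
    flagged invalid are dropped.  Requires >= 3 usable points.
    """
    conc = series.concentrations()
    xs, ys = [], []
    flags: list[str] = []
    for group in standards:
        if group.dilution not in conc:
            continue
        kept, gflags = filter_replicates(group, sd_threshold)
        if "invalid" in gflags or not kept:
            flags.append(f"dropped_dilution:{group.dilution}")
            continue
        xs.append(float(np.mean(kept)))
        ys.append(np.log10(conc[group.dilution]))
    if len(xs) < 3:
        raise ValueError(
            f"standard curve needs >= 3 valid dilution points, got {len(xs)}"
        )
    order = np.argsort(xs)
    xs_arr, ys_arr = np.asarray(xs)[order], np.asarray(ys)[order]
    if np.any(np.diff(ys_arr) > 0):  # Ct up should mean concentration down
        flags.append("non_monotonic")
    fit = stats.linregress(xs_arr, ys_arr)
    return StandardCurve(
        m=float(fit.slope),
        b=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(xs),
        ct_range=(float(xs_arr.min()), float(xs_arr.max())),
        flags=tuple(flags),
    )


def ct_to_ng(ct: float, curve: StandardCurve) -> tuple[float, list[str]]:
    """Invert the standard curve: ng = 10^(m·Ct + b).

    Extrapolation beyond the fitted Ct range is allowed but flagged.
    """
    flags = []
    if not curve.ct_range[0] <= ct <= curve.ct_range[1]:
        flags.append("extrapolated")
    return 10.0 ** (curve.m * ct + curve.b), flags


def ng_to_copies(ng: float, params: WorkflowParams) -> float:
    """Molecule count in the reaction from nanograms of ssDNA-equivalent.

    copies = ng · N_A / (amplicon bp · 330 g/mol · 1e9 ng/g).
    """
    if ng < 0:
        raise ValueError("ng must be non-negative")
    return (
        ng
        * params.avogadro
        / (params.amplicon_length_bp * params.nt_mass_g_per_mol * params.ng_per_g)
    )


def copies_per_ul_prep(copies_rxn: float, params: WorkflowParams) -> float:
    """Scale reaction-level copies to copies per μL of eVLP preparation.

    The chain: × cDNA dilution factor × cDNA reaction volume ÷ RNA volume
    used in cDNA synthesis × RNA elution volume ÷ prep volume extracted.
    The dilution correction is applied exactly once, here.
    """
    return (
        copies_rxn
        * params.cdna_dilution_factor
        * params.cdna_reaction_volume_ul
        / params.rna_volume_ul
        * params.elution_volume_ul
        / params.prep_volume_ul
    )


def quantify_sample(
    group: CtReplicateGroup,
    curve: StandardCurve,
    params: WorkflowParams,
    sd_threshold: float = 0.5,
) -> PrepTiter:
    """Full per-sample pipeline: QC -> mean Ct -> ng -> copies -> prep titer."""
    kept, flags = filter_replicates(group, sd_threshold)
    if "invalid" in flags or not kept:
        return PrepTiter(group.sample, float("nan"), float("nan"), tuple(flags) + ("non_quantifiable",))
    mean_ct = float(np.mean(kept))
    ng, ct_flags = ct_to_ng(mean_ct, curve)
    copies_rxn = ng_to_copies(ng, params)
    return PrepTiter(
        sample=group.sample,
        copies_per_ul_reaction=copies_rxn,
        copies_per_ul_prep=copies_per_ul_prep(copies_rxn, params),
        flags=tuple(flags + ct_flags),
    )


def quantify_plate(
    df: pd.DataFrame,
    series: DilutionSeries,
    params: WorkflowParams,
    target: str | None = None,
    sd_threshold: float = 0.5,
) -> tuple[pd.DataFrame, StandardCurve]:
    """Quantify every test/noRT sample on a plate against its own standards.

    Returns a tidy titer table and the fitted curve.  The curve is fitted
    from this plate's ``standard`` rows only (curves are never reused
    across runs).
    """
    if target is not None:
        df = df[df["target"] == target]
    groups = groups_from_plate(df)
    standards = [g for g in groups if g.role == "standard"]
    curve = fit_standard_curve(standards, series, sd_threshold)
    rows = []
    for group in groups:
        if group.role not in ("test", "noRT"):
            continue
        titer = quantify_sample(group, curve, params, sd_threshold)
        rows.append(
            {
                "sample": group.sample,
                "role": group.role,
                "copies_per_ul_reaction": titer.copies_per_ul_reaction,
                "copies_per_ul_prep": titer.copies_per_ul_prep,
                "flags": ";".join(titer.flags),
            }
        )
    return pd.DataFrame(rows), curve


def plasmid_load_per_genome(
    plasmid_group: CtReplicateGroup,
    control_group: CtReplicateGroup,
    plasmid_curve: StandardCurve,
    control_curve: StandardCurve,
    plasmid_params: WorkflowParams,
    control_params: WorkflowParams,
    control_copies_per_genome: float = 2.0,
    sd_threshold: float = 0.5,
) -> GenomeNormalizedLoad:
    """Plasmid copies per 100 genomes via an internal control gene.

    Plasmid and control (e.g. RPLP0) copies are each computed against their
    own curve and amplicon length; genome count = control copies divided by
    the control's copies per genome (2 for an autosomal diploid gene).
    """
    flags: list[str] = []

    def copies(group, curve, params):
        kept, gflags = filter_replicates(group, sd_threshold)
        if "invalid" in gflags or not kept:
            return None, gflags
        ng, ct_flags = ct_to_ng(float(np.mean(kept)), curve)
        return ng_to_copies(ng, params), gflags + ct_flags

    control_copies, cflags = copies(control_group, control_curve, control_params)
    flags += [f"control_{f}" for f in cflags]
    if not control_copies:  # None or zero signal
        return GenomeNormalizedLoad(
            plasmid_group.sample, float("nan"), control_group.target,
            control_copies_per_genome, tuple(flags) + ("non_quantifiable",),
        )
    plasmid_copies, pflags = copies(plasmid_group, plasmid_curve, plasmid_params)
    flags += pflags
    if plasmid_copies is None:
        plasmid_copies = 0.0
        flags.append("plasmid_nd")
    genomes = control_copies / control_copies_per_genome
    return GenomeNormalizedLoad(
        sample=plasmid_group.sample,
        copies_per_100_genomes=100.0 * plasmid_copies / genomes,
        control_gene=control_group.target,
        control_copies_per_genome=control_copies_per_genome,
        flags=tuple(flags),
    )
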