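"""Batch standardization by dose adjustment.

Independent eVLP preparations vary in titer, so transducing equal volumes
delivers unequal amounts of particles.  Given a per-prep quantification
metric — sgRNA copies/μL from the qPCR assay or RLU/μL from the lytic
split-luciferase assay — this module computes the volume of each prep that
delivers the same metric amount as a chosen reference prep at a chosen
reference volume: adjusted_volume_i = ref_volume × value_ref / value_i,
after rescaling metrics measured at different dilutions onto an undiluted
basis.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PrepMetric", "DoseAdjustment", "adjust_doses", "delivered_amount"]


@dataclass(frozen=True)
class PrepMetric:
    """One prep's quantification value.

    ``dilution`` is the fold-dilution at which the value was measured
    (1 = undiluted); the undiluted-basis value is ``value * dilution``.
    """

    prep: str
    kind: str  # volume | sgRNA_copies_per_ul | rlu_per_ul
    value: float
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("metric value must be non-negative")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")

    @property
    def undiluted_value(self) -> float:
        return self.value * self.dilution


@dataclass(frozen=True)
class DoseAdjustment:
    reference: str
    reference_volume_ul: float
    volumes_ul: dict[str, float]
    metric_values: dict[str, float]  # undiluted basis
    capped: tuple[str, ...] = ()
    excluded: tuple[str, ...] = ()


def adjust_doses(
    metrics: list[PrepMetric],
    reference: str,
    reference_volume_ul: float = 1.0,
    max_volume_ul: float | None = None,
) -> DoseAdjustment:
    """Volumes that equalize the delivered metric amount across preps.

    All metrics must share one kind.  A prep with value 0 cannot be
    normalized and is excluded with a flag; volumes above ``max_volume_ul``
    are capped and flagged rather than silently truncated.
    """
    if reference_volume_ul <= 0:
        raise ValueError("reference volume must be positive")
    kinds = {m.kind for m in metrics}
    if len(kinds) > 1:
        raise ValueError(f"mixed metric kinds: {sorted(kinds)}")
    by_prep = {m.prep: m for m in metrics}
    if reference not in by_prep:
        raise ValueError(f"reference prep {reference!r} not among metrics")
    ref_value = by_prep[reference].undiluted_value
    if ref_value <= 0:
        raise ValueError("reference prep has zero metric value")

    volumes: dict[str, float] = {}
    values: dict[str, float] = {}
    capped: list[str] = []
    excluded: list[str] = []
    for m in metrics:
        values[m.prep] = m.undiluted_value
        if m.undiluted_value == 0:
            excluded.append(m.prep)
            continue
        vol = reference_volume_ul * ref_value / m.undiluted_value
        if max_volume_ul is not None and vol > max_volume_ul:
            vol = max_volume_ul
            capped.append(m.prep)
        volumes[m.prep] = vol
    return DoseAdjustment(
        reference=reference,
        reference_volume_ul=reference_volume_ul,
        volumes_ul=volumes,
        metric_values=values,
        capped=tuple(capped),
        excluded=tuple(excluded),
    )


def delivered_amount(adjustment: DoseAdjustment) -> dict[str, float]:
    """Metric amount each adjusted dose delivers (volume × undiluted value).

    Equal across uncapped preps by construction; capped preps fall short.
    """
    return {
        prep: vol * adjustment.metric_values[prep]
        for prep, vol in adjustment.volumes_ul.items()
    }
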