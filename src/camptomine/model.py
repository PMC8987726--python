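"""Core domain objects: fragment peaks, MS/MS spectra and the known-compound
registry record shared by the I/O, rule-engine and synthetic modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .formula import ElementalFormula, ion_mz


@dataclass(frozen=True)
class FragmentPeak:
    """A centroided product-ion peak.

    ``synthetic`` marks peaks that were reconstructed from a described
    neutral-loss chain rather than printed/measured directly.
    """

    mz: float
    intensity: float = 0.0
    synthetic: bool = False

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class IonSpectrum:
    """One precursor ion with its fragment peaks.

    Invariants enforced on construction: peaks sorted ascending by m/z, no
    fragment above precursor + 1 Th, polarity is '+' or '-'.  Retention time
    is in minutes and optional.  ``metadata`` carries free-form annotations
    (compound name, stated ion formula, fixture series, ...).
    """

    id: str
    precursor_mz: float
    polarity: str
    retention_time: Optional[float] = None
    peaks: List[FragmentPeak] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        for p in self.peaks:
            if p.mz > self.precursor_mz + 1.0:
                raise ValueError(
                    f"{self.id}: fragment {p.mz} exceeds precursor "
                    f"{self.precursor_mz} + 1.0"
                )

    @property
    def mz_array(self) -> List[float]:
        return [p.mz for p in self.peaks]

    def base_peak(self) -> Optional[FragmentPeak]:
        return max(self.peaks, key=lambda p: p.intensity, default=None)


@dataclass(frozen=True)
class KnownCompoundRecord:
    """A previously characterized compound in the reference registry.

    ``formula`` is the formula of the *ion* as printed ([M+H]+ / [M-H]-
    species with the proton included), so its theoretical m/z follows
    directly from :func:`camptomine.formula.ion_mz`.
    """

    id: str
    name: str
    formula: ElementalFormula
    group: str
    source: str = ""
    polarity: str = "+"

    VALID_GROUPS = ("CG", "PG", "SG", "VG", "VC", "IP", "TP")

    def __post_init__(self) -> None:
        if self.group not in self.VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.id}")

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(self.formula, self.polarity)
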