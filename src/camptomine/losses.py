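"""The neutral-loss catalog used by the rule engine and the spectrum
simulator.

Each catalog entry pairs a loss formula with its nominal (integer) mass:
the rule engine can match fragment-pair mass differences either at exact
mass within a ppm tolerance or at nominal mass within ±0.5 Da.  Nominal 42
is deliberately ambiguous (propene vs ketene); both entries are kept and
the closer exact mass wins when attributing an edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

from .formula import ElementalFormula, monoisotopic_mass


@dataclass(frozen=True)
class NeutralLoss:
    name: str
    formula: ElementalFormula
    nominal: int
    exact: float

    def __post_init__(self) -> None:
        if abs(self.exact - monoisotopic_mass(self.formula)) > 1e-4:
            raise ValueError(
                f"loss {self.name}: exact mass {self.exact} inconsistent "
                f"with formula {self.formula}"
            )
        if self.nominal != round(self.exact):
            raise ValueError(f"loss {self.name}: nominal != round(exact)")


def _load() -> Tuple[Tuple[NeutralLoss, ...], Dict[str, NeutralLoss]]:
    text = (resources.files("camptomine") / "data" / "loss_catalog.tsv").read_text()
    rows = text.strip().splitlines()
    header = rows[0].split("\t")
    catalog: List[NeutralLoss] = []
    by_key: Dict[str, NeutralLoss] = {}
    for line in rows[1:]:
        d = dict(zip(header, line.split("\t")))
        f = ElementalFormula.parse(d["formula"])
        loss = NeutralLoss(
            name=d["name"],
            formula=f,
            nominal=int(d["nominal"]),
            exact=round(monoisotopic_mass(f), 6),
        )
        catalog.append(loss)
        by_key[d["formula"]] = loss  # keyed as written in the catalog file
    return tuple(catalog), by_key


DEFAULT_CATALOG, LOSS_BY_FORMULA = _load()
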