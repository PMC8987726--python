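"""The packaged in-study spectrum fixture.

Sixty-four characterized metabolites from elicited *Camptotheca acuminata*
plantlets: 40 alkaloids of the camptothecin (CG), pumiloside (PG),
strictosidinic acid (SG), vincosamide/strictosamide (VG) and
vincosamide–camptothecin hybrid (VC) series, 9 iridoid-pathway precursors
(IP1–IP9) and 15 tryptamine-pathway precursors (TP1–TP15), together with a
25-compound registry of the previously known alkaloids.

Printed precursor and fragment m/z values are stored verbatim, including a
handful of typographical outliers that disagree with their stated ion
formulas at exact-mass level (they remain consistent at nominal/integer
mass, which is why the rule engine runs in nominal mode on this fixture).
Fragments that the narrative describes only as a loss chain are
reconstructed by subtracting exact loss masses from the precursor and are
flagged ``synthetic``; compounds whose precursor m/z was never printed use
the theoretical m/z of their stated ion formula.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from .formula import ElementalFormula, ion_mz
from .losses import LOSS_BY_FORMULA
from .model import FragmentPeak, IonSpectrum, KnownCompoundRecord

# ---------------------------------------------------------------------------
# Compound table
# ---------------------------------------------------------------------------
# Each chain is a dict: optional "start" (printed m/z of an existing peak to
# branch from; default = precursor) and "steps", a list of
# (loss key in the catalog, printed child m/z or None → synthesize).
# "peaks" holds standalone fragments: (m/z, synthetic?).

_C = lambda steps, start=None: {"start": start, "steps": steps}

_ALKALOIDS: List[dict] = [
    # --- camptothecin group (diagnostic m/z 168) ---------------------------
    dict(id="CG1", name="9-methoxycamptothecin", group="CG", rt=None,
         formula="C21H19N2O5", mz=None, known=True,
         chains=[_C([("CO2", None), ("C3H4O", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG2", name="10-methoxycamptothecin", group="CG", rt=None,
         formula="C21H19N2O5", mz=None, known=True,
         chains=[_C([("C3H4O", None), ("CO2", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG3", name="16-hydroxy-15,16-dihydrocamptothecoside", group="CG",
         rt=None, formula="C26H31N2O11", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("H2O", None), ("CO2", None),
                     ("C3H4O", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG4", name="deoxypumiloside", group="CG", rt=None,
         formula="C26H29N2O8", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("C3H4O", None), ("CO2", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG5", name="10-hydroxycamptothecin", group="CG", rt=None,
         formula="C20H17N2O5", mz=None, known=True,
         chains=[_C([("CO2", None), ("C3H4O", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG7", name="camptothecoside", group="CG", rt=None,
         formula="C26H29N2O10", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("CO2", None), ("C3H4O", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG8", name="camptothecin", group="CG", rt=None,
         formula="C20H17N2O4", mz=None, known=True,
         chains=[_C([("CO2", None), ("C3H4O", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG9", name="18,19-dehydrocamptothecin", group="CG", rt=None,
         formula="C20H15N2O4", mz=None, known=True,
         chains=[_C([("CO2", None), ("C3H4O", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG11", name="20-deoxycamptothecin", group="CG", rt=None,
         formula="C20H17N2O3", mz=None, known=True,
         chains=[_C([("C3H4O", None), ("CO2", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG12", name="20-deoxycamptothecin isomer", group="CG", rt=None,
         formula="C20H17N2O3", mz=None, known=True,
         chains=[_C([("C3H4O", None), ("CO2", None)])],
         peaks=[(168.0690, True)]),
    dict(id="CG14", name="5-hydroxycamptothecin", group="CG", rt=9.50,
         formula="C20H17N2O5", mz=365.1137, known=True,
         chains=[_C([("H2O", None), ("CO2", None), ("C3H4O", None)])],
         peaks=[(168.0690, False)]),
    # --- pumiloside group (diagnostic m/z 158) -----------------------------
    dict(id="PG2", name="2-hydroxypumiloside", group="PG", rt=None,
         formula="C26H31N2O10", mz=None, known=True,
         chains=[_C([("C6H10O5", 369.1434), ("H2O", None), ("C4H6O", None),
                     ("C5H4O2", None)])],
         peaks=[(158.0597, True)]),
    dict(id="PG3", name="pumiloside", group="PG", rt=None,
         formula="C26H29N2O9", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(158.0597, True)]),
    dict(id="PG4", name="pumiloside isomer", group="PG", rt=None,
         formula="C26H29N2O9", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(158.0597, True)]),
    dict(id="PG5", name="strictosamide ketolactam", group="PG", rt=None,
         formula="C26H31N2O9", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(158.0597, True)]),
    dict(id="PG6", name="2-hydroxypumiloside aglycone", group="PG", rt=10.98,
         formula="C20H21N2O5", mz=369.2227, known=False,
         chains=[_C([("H2O", None), ("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(158.0597, True)]),
    dict(id="PG7", name="21-methoxypumiloside aglycone", group="PG", rt=10.04,
         formula="C21H23N2O5", mz=383.2038, known=False,
         chains=[_C([("CH4O", 351.1341), ("C4H6O", None), ("C5H4O2", None)]),
                 _C([("H2O", None), ("CH4O", None)])],
         peaks=[(158.0597, False)]),
    # --- strictosidinic acid group (diagnostic m/z 144) --------------------
    dict(id="SG1", name="strictosidinic acid isomer 1", group="SG", rt=None,
         formula="C26H33N2O9", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("NH3", None), ("C4H6O", None)])],
         peaks=[(144.0808, True)]),
    dict(id="SG2", name="strictosidinic acid isomer 2", group="SG", rt=None,
         formula="C26H33N2O9", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("NH3", None), ("C4H6O", None)])],
         peaks=[(144.0808, True)]),
    dict(id="SG3", name="strictosidinic acid", group="SG", rt=None,
         formula="C26H33N2O9", mz=517.2181, known=True,
         chains=[_C([("C6H10O5", 355.1641), ("NH3", None), ("C4H6O", None)])],
         peaks=[(144.0808, True)]),
    dict(id="SG4", name="4-hydroxystrictosidinic acid aglycone", group="SG",
         rt=7.91, formula="C20H23N2O5", mz=371.1650, known=False,
         chains=[_C([("O", None), ("NH3", None), ("C4H6O", None),
                     ("C6H4O3", 144.0811)])],
         peaks=[]),
    dict(id="SG5", name="7-hydroxystrictosidinic acid", group="SG", rt=8.19,
         formula="C26H35N2O10", mz=535.2327, known=False,
         chains=[_C([("H2O", 517.2181), ("C6H10O5", None), ("NH3", None),
                     ("C4H6O", None)])],
         peaks=[(144.0808, True)]),
    # --- vincosamide / strictosamide group (diagnostic m/z 144) ------------
    dict(id="VG1", name="strictosamide diol", group="VG", rt=None,
         formula="C26H33N2O10", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("H2O", None), ("C4H6O", None),
                     ("C5H4O2", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VG2", name="strictosamide epoxide", group="VG", rt=None,
         formula="C26H31N2O9", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VG4", name="3,14-dehydrostrictosamide", group="VG", rt=None,
         formula="C26H29N2O8", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VG5", name="vincosamide", group="VG", rt=None,
         formula="C26H31N2O8", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VG6", name="strictosamide", group="VG", rt=None,
         formula="C26H31N2O8", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VG7", name="strictothecin", group="VG", rt=None,
         formula="C20H17N2O4", mz=None, known=True,
         chains=[_C([("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VG8", name="7-hydroxy-3,14-dehydrostrictosamide", group="VG",
         rt=8.43, formula="C26H31N2O9", mz=515.2002, known=False,
         chains=[_C([("C6H10O5", 353.1462), ("H2O", 335.1406),
                     ("C4H6O", 265.0981)]),
                 _C([("C4H6O", 283.1076), ("C5H4O2", None)], start=353.1462),
                 _C([("CO", None), ("CO", None)], start=283.1076),
                 _C([("H2O", None)])],
         peaks=[(144.0816, False)]),
    dict(id="VG9", name="7-hydroxy-3,14-dehydrostrictosamide aglycone",
         group="VG", rt=9.13, formula="C20H21N2O4", mz=353.1470, known=False,
         chains=[_C([("H2O", None), ("C4H6O", None)]),
                 _C([("C4H6O", None), ("C5H4O2", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VG10", name="10-hydroxystrictosamide 6'-O-β-D-glucopyranoside",
         group="VG", rt=9.21, formula="C32H41N2O14", mz=677.2607, known=False,
         chains=[_C([("C6H10O5", None), ("C6H10O5", None), ("C4H6O", None),
                     ("C5H4O2", None)])],
         peaks=[(160.0749, True), (144.0800, False)]),
    dict(id="VG11", name="7,21-dihydroxystrictosamide aglycone", group="VG",
         rt=9.83, formula="C20H25N2O5", mz=373.1847, known=False,
         chains=[_C([("H2O", 355.1292), ("H2O", 337.1136), ("C4H6O", None)]),
                 _C([("C4H6O", None)], start=355.1292)],
         peaks=[(144.0819, False)]),
    dict(id="VG12", name="2-hydroxy-6,7-dehydrostrictosamide", group="VG",
         rt=10.02, formula="C26H31N2O9", mz=515.2041, known=False,
         chains=[_C([("C6H10O5", 353.1483), ("C4H6O", 283.1092)]),
                 _C([("H2O", None)]),
                 _C([("H2O", None)], start=353.1483),
                 _C([("H2O", None)], start=283.1092)],
         peaks=[(160.0760, False), (144.0801, False)]),
    dict(id="VG13", name="21-methoxystrictosamide epoxide aglycone",
         group="VG", rt=11.09, formula="C21H25N2O5", mz=385.1762, known=False,
         chains=[_C([("CH4O", 353.1472), ("C4H6O", None)])],
         peaks=[(144.0815, False)]),
    # --- vincosamide-camptothecin hybrid group (diagnostic m/z 144) --------
    dict(id="VC5", name="glucosyl strictothecin analog", group="VC", rt=None,
         formula="C27H29N2O11", mz=None, known=True,
         chains=[_C([("C6H10O5", None), ("H2O", None), ("CO2", None),
                     ("CO", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VC6", name="18-methoxy-20-dehydroxystrictothecin", group="VC",
         rt=9.06, formula="C20H21N2O5", mz=369.1922, known=False,
         chains=[_C([("CH4O", None), ("CO2", None), ("C3H6", None)])],
         peaks=[(144.0818, False)]),
    dict(id="VC7", name="VC4 aglycone", group="VC", rt=9.31,
         formula="C19H21N2O2", mz=309.1581, known=False,
         chains=[_C([("CO2", None), ("C3H4O", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VC8", name="6-O-β-glucopyranosyl-18,19-dehydrostrictothecin",
         group="VC", rt=9.44, formula="C26H27N2O10", mz=527.1681, known=False,
         chains=[_C([("C6H10O5", None), ("H2O", None), ("CO2", None),
                     ("CO", None)])],
         peaks=[(144.0808, True)]),
    dict(id="VC9", name="10-hydroxystrictothecin", group="VC", rt=10.06,
         formula="C20H17N2O5", mz=365.1137, known=False,
         chains=[_C([("CO2", None), ("C3H4O", None)]),
                 _C([("O", 221.0716)], start=237.0665)],
         peaks=[(237.0665, True), (144.0801, False)]),
    dict(id="VC10", name="6-hydroxy-18,19-dehydrostrictothecin", group="VC",
         rt=10.20, formula="C20H17N2O5", mz=365.1134, known=False,
         chains=[_C([("H2O", None), ("CO2", None), ("C3H4O", None)])],
         peaks=[(144.0808, True)]),
]

_IRIDOIDS: List[dict] = [
    dict(id="IP1", name="geraniol", group="IP", rt=10.92, polarity="+",
         formula="C10H19O", mz=155.0856, known=True, chains=[],
         peaks=[(141.0140, False), (137.0957, False), (127.0344, False),
                (123.0028, False), (109.1019, False)]),
    dict(id="IP2", name="10-hydroxygeraniol", group="IP", rt=7.71,
         polarity="+", formula="C10H19O2", mz=171.0919, known=True,
         chains=[_C([("CH2", None), ("CH2", None), ("H2O", None),
                     ("H2O", None)])],
         peaks=[]),
    dict(id="IP3", name="10-oxogeranial", group="IP", rt=7.12, polarity="+",
         formula="C10H15O2", mz=167.0701, known=True,
         chains=[_C([("CH2", None), ("CO", None), ("CO", 97.0653)])],
         peaks=[]),
    dict(id="IP4", name="iridodial", group="IP", rt=0.50, polarity="-",
         formula="C10H15O2", mz=167.0337, known=True,
         chains=[_C([("CH2", 153.0194), ("H2", 151.0053)]),
                 _C([("C3H2O", None)])],
         peaks=[(83.0500, False)]),
    dict(id="IP5", name="iridotrial", group="IP", rt=6.71, polarity="+",
         formula="C10H15O3", mz=183.1021, known=True,
         chains=[_C([("CO", None)]),
                 _C([("CH2", None), ("CO", None)])],
         peaks=[]),
    dict(id="IP6", name="7-deoxyloganetic acid", group="IP", rt=11.82,
         polarity="-", formula="C10H13O4", mz=197.1185, known=True,
         chains=[_C([("CO2", None), ("H2O", None)]),
                 _C([("H2", None), ("C3H2O", None)])],
         peaks=[(97.0653, False)]),
    dict(id="IP7", name="7-deoxyloganic acid", group="IP", rt=6.33,
         polarity="+", formula="C16H25O9", mz=361.1391, known=True,
         chains=[_C([("C6H10O5", None), ("CO2", None)])],
         peaks=[]),
    dict(id="IP8", name="loganic acid", group="IP", rt=1.90, polarity="-",
         formula="C16H23O10", mz=375.1273, known=True,
         chains=[_C([("C6H10O5", None), ("CO2", None), ("H2", None),
                     ("C3H2O", 113.0245)])],
         peaks=[]),
    dict(id="IP9", name="secologanic acid", group="IP", rt=2.96,
         polarity="-", formula="C16H21O10", mz=373.1152, known=True,
         chains=[_C([("C6H10O5", None), ("CO2", None)])],
         peaks=[(183.0274, False), (139.0373, False), (121.0653, False)]),
]

_TRYPTAMINES: List[dict] = [
    dict(id="TP1", name="D-erythrose 4-phosphate", group="TP", rt=9.83,
         polarity="-", formula="C4H8O7P", mz=199.1334, known=True,
         chains=[_C([("CO", None), ("H2O", None), ("H2O", None)]),
                 _C([("H2O", None)])],
         peaks=[]),
    dict(id="TP2", name="3-deoxy-D-arabinose-heptulosonate 7-phosphate",
         group="TP", rt=7.86, polarity="-", formula="C7H12O10P",
         mz=287.1046, known=True,
         chains=[_C([("CO2", None), ("CO", 215.1195)]),
                 _C([("HPO3", 207.1039)]),
                 _C([("H2O", None)])],
         peaks=[]),
    dict(id="TP3", name="3-dehydroquinic acid", group="TP", rt=3.23,
         polarity="-", formula="C7H9O6", mz=189.0063, known=True,
         chains=[_C([("CO2", None), ("CO", None), ("H2O", None),
                     ("H2O", None)])],
         peaks=[]),
    dict(id="TP4", name="3-dehydroshikimic acid", group="TP", rt=4.65,
         polarity="-", formula="C7H7O5", mz=171.1019, known=True,
         chains=[_C([("CO2", None), ("CO", None), ("H2O", None)])],
         peaks=[]),
    dict(id="TP5", name="shikimate", group="TP", rt=1.11, polarity="-",
         formula="C7H9O5", mz=173.0086, known=True,
         chains=[_C([("CO2", None), ("H2O", None), ("H2O", None)])],
         peaks=[]),
    dict(id="TP6", name="3-phosphonatoshikimate", group="TP", rt=10.01,
         polarity="-", formula="C7H10O8P", mz=253.1433, known=True,
         chains=[_C([("H3PO4", 155.1077)]),
                 _C([("CO2", None), ("H2O", None)])],
         peaks=[]),
    dict(id="TP7", name="5-O-(1-carboxyvinyl)-3-phosphoshikimate",
         group="TP", rt=12.96, polarity="-", formula="C10H12O10P",
         mz=323.1753, known=True,
         chains=[_C([("CO2", None), ("CO2", None), ("H2O", None),
                     ("HPO3", None), ("CH2", None)])],
         peaks=[]),
    dict(id="TP8", name="chorismic acid", group="TP", rt=9.14, polarity="-",
         formula="C10H9O6", mz=225.1127, known=True,
         chains=[_C([("CO2", None), ("CO2", None), ("H2O", None)])],
         peaks=[]),
    dict(id="TP9", name="anthranilate", group="TP", rt=8.75, polarity="+",
         formula="C7H8NO2", mz=138.0556, known=True,
         chains=[_C([("H2O", None), ("CO", None)])],
         peaks=[]),
    dict(id="TP10", name="5-phosphoribosyl anthranilate", group="TP",
         rt=14.76, polarity="+", formula="C12H17NO9P", mz=350.2807,
         known=True,
         chains=[_C([("CO2", None), ("HPO3", None)]),
                 _C([("C3H6O3", None), ("CHO", None)]),
                 _C([("CO", None)])],
         peaks=[(151.0962, False)]),
    dict(id="TP11",
         name="1-(2-carboxyphenylamino)-1-deoxy-D-ribulose 5-phosphate",
         group="TP", rt=None, polarity="+", formula="C12H17NO9P",
         mz=350.2807, known=True,
         chains=[_C([("CO", None), ("CO2", None)])],
         peaks=[]),
    dict(id="TP12", name="indole-3-glycerol phosphate", group="TP", rt=12.43,
         polarity="+", formula="C11H15NO6P", mz=288.1799, known=True,
         chains=[_C([("C2H7O5P", None)]),
                 _C([("H2O", None), ("CO", None)])],
         peaks=[(130.0857, False), (116.0702, False)]),
    dict(id="TP13", name="indole", group="TP", rt=None, polarity="+",
         formula="C8H8N", mz=None, known=True, chains=[],
         peaks=[(91.0542, True)]),
    dict(id="TP14", name="tryptophan", group="TP", rt=6.34, polarity="+",
         formula="C11H13N2O2", mz=205.0119, known=True,
         chains=[_C([("CO2", None), ("NH3", None)])],
         peaks=[(118.0646, False)]),
    dict(id="TP15", name="tryptamine", group="TP", rt=6.54, polarity="+",
         formula="C10H13N2", mz=161.1069, known=True,
         chains=[_C([("NH3", None)])],
         peaks=[(117.0573, True)]),
]

#: Ids of the 25 previously known alkaloids forming the reference registry.
_KNOWN_ALKALOID_IDS = tuple(
    rec["id"] for rec in _ALKALOIDS if rec["known"]
)


def _build_spectrum(rec: dict) -> IonSpectrum:
    formula = ElementalFormula.parse(rec["formula"])
    polarity = rec.get("polarity", "+")
    precursor = rec["mz"]
    printed_precursor = precursor is not None
    if precursor is None:
        precursor = round(ion_mz(formula, polarity), 4)
    peaks: Dict[float, FragmentPeak] = {}

    def add(mz: float, intensity: float, synthetic: bool) -> None:
        # keep the strongest annotation if the same m/z appears twice
        prev = peaks.get(round(mz, 4))
        if prev is None or intensity > prev.intensity:
            peaks[round(mz, 4)] = FragmentPeak(
                mz=round(mz, 4), intensity=intensity, synthetic=synthetic)

    for chain in rec["chains"]:
        current = chain["start"] if chain["start"] is not None else precursor
        intensity = 500.0
        for loss_key, printed in chain["steps"]:
            loss = LOSS_BY_FORMULA[loss_key]
            mz = printed if printed is not None else current - loss.exact
            add(mz, intensity, synthetic=printed is None)
            current = mz
            intensity *= 0.8
    for mz, synthetic in rec["peaks"]:
        # standalone peaks; diagnostic-series ions get base-peak intensity
        intensity = 1000.0 if mz < 170.0 else 200.0
        add(mz, intensity, synthetic=synthetic)
    series = {"CG": "alkaloid", "PG": "alkaloid", "SG": "alkaloid",
              "VG": "alkaloid", "VC": "alkaloid",
              "IP": "iridoid", "TP": "tryptamine"}[rec["group"]]
    return IonSpectrum(
        id=rec["id"],
        precursor_mz=precursor,
        polarity=polarity,
        retention_time=rec["rt"],
        peaks=sorted(peaks.values(), key=lambda p: p.mz),
        metadata={
            "name": rec["name"],
            "group": rec["group"],
            "series": series,
            "ion_formula": rec["formula"],
            "known": rec["known"],
            "precursor_printed": printed_precursor,
        },
    )


def paper_fixture() -> Tuple[List[IonSpectrum], List[KnownCompoundRecord]]:
    """Return the 64 fixture spectra and the 25-compound known registry.

    Spectra carry ``metadata['series']`` in {'alkaloid', 'iridoid',
    'tryptamine'} and ``metadata['group']`` in {CG, PG, SG, VG, VC, IP, TP};
    the registry holds the previously known alkaloids only.
    """
    spectra = [_build_spectrum(r) for r in _ALKALOIDS + _IRIDOIDS + _TRYPTAMINES]
    registry = [
        KnownCompoundRecord(
            id=rec["id"],
            name=rec["name"],
            formula=ElementalFormula.parse(rec["formula"]),
            group=rec["group"],
            source="prior-study",
            polarity=rec.get("polarity", "+"),
        )
        for rec in _ALKALOIDS
        if rec["id"] in _KNOWN_ALKALOID_IDS
    ]
    return spectra, registry


def alkaloid_spectra(spectra: Optional[Sequence[IonSpectrum]] = None
                     ) -> List[IonSpectrum]:
    """The 40 alkaloid-series fixture spectra (CG/PG/SG/VG/VC)."""
    if spectra is None:
        spectra, _ = paper_fixture()
    return [s for s in spectra if s.metadata.get("series") == "alkaloid"]
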