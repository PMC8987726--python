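"""Synthetic-data generators with known ground truth.

Every stage of the pipeline gets a no-download test bed:

* ``gen_spectra`` — fragmentation spectra of scaffold+substituent
  alkaloids built from the group rules and the loss catalog, with ppm mass
  jitter and spurious peaks that are guaranteed not to mimic catalog
  losses;
* ``gen_expression`` — a CK/MeJa/AgNO3/PEG × 3-replicate FPKM-like matrix
  with planted co-expression modules (mutually orthogonal latent drivers),
  designated bait/CYP450 genes and treatment-specific upregulation;
* ``gen_metabolites`` — a two-group metabolite-abundance table with
  planted log2 effects.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formula import ElementalFormula, ion_mz
from .fragrules import DEFAULT_RULES, GroupRule
from .losses import DEFAULT_CATALOG, LOSS_BY_FORMULA
from .model import FragmentPeak, IonSpectrum

CONDITIONS = ("CK", "MeJa", "AgNO3", "PEG")

# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

#: Scaffold ion formulas per alkaloid group (protonated species).
_SCAFFOLDS = {
    "CG": "C20H17N2O4",
    "PG": "C26H29N2O9",
    "SG": "C26H33N2O9",
    "VG": "C26H31N2O8",
    "VC": "C20H17N2O5",
}

#: Loss-chain building blocks per group: the slots that must appear.
_REQUIRED_CHOICES = {
    "CG": [["C3H4O"], ["C4H6O"], ["C3H4O", "CO2"]],
    "PG": [["C4H6O", "C5H4O2"]],
    "SG": [["NH3", "C4H6O"]],
    "VG": [["C4H6O", "C5H4O2"]],
    "VC": [["CO2", "C3H4O"], ["CO2", "C3H6"]],
}


@dataclass(frozen=True)
class SpectrumTruth:
    spectrum_id: str
    group: str
    ion_formula: str
    glucosyl_count: int
    hydroxy_first_step: bool
    methoxy: bool
    loss_chain: Tuple[str, ...]


def _diag_windows(rules: Sequence[GroupRule]) -> List[float]:
    out = []
    for r in rules:
        out.append(r.diagnostic_exact)
        out.append(r.diagnostic_exact + 15.9949)  # hydroxylated-core window
    return out


def gen_spectra(
    n: int,
    group_mix: Optional[Mapping[str, float]] = None,
    ppm_noise: float = 5.0,
    spurious_rate: float = 0.05,
    seed: int = 0,
    rules: Sequence[GroupRule] = DEFAULT_RULES,
) -> Tuple[List[IonSpectrum], List[SpectrumTruth]]:
    """Simulate ``n`` alkaloid MS/MS spectra with known classification truth.

    Each spectrum applies the group's diagnostic ion and an admissible
    loss chain (optional glucosyl/hydroxy/methoxy units extend both the
    ion formula and the chain) to the scaffold formula, jitters every m/z
    by N(0, ppm_noise) and injects spurious peaks at ``spurious_rate`` per
    true peak.  Spurious peaks are resampled until they form no
    catalog-compatible loss relation (±0.7 Da of any nominal) with any
    other peak or the precursor and sit outside all diagnostic windows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    groups = list(_SCAFFOLDS)
    if group_mix is None:
        probs = np.ones(len(groups)) / len(groups)
    else:
        probs = np.array([group_mix.get(g, 0.0) for g in groups], float)
        probs = probs / probs.sum()
    rule_by_group = {r.group: r for r in rules}
    nominals = sorted({l.nominal for l in DEFAULT_CATALOG})
    diag_mzs = _diag_windows(rules)

    spectra: List[IonSpectrum] = []
    truths: List[SpectrumTruth] = []
    for i in range(n):
        group = groups[rng.choice(len(groups), p=probs)]
        formula = ElementalFormula.parse(_SCAFFOLDS[group])
        chain: List[str] = []
        hydroxy = bool(rng.random() < 0.3)
        methoxy = bool(rng.random() < 0.2)
        n_glc = int(rng.choice([0, 1, 2], p=[0.5, 0.3, 0.2]))
        if hydroxy:
            chain.append("H2O")
            formula = formula + LOSS_BY_FORMULA["H2O"].formula
        if methoxy:
            chain.append("CH4O")
            formula = formula + LOSS_BY_FORMULA["CH4O"].formula
        chain += ["C6H10O5"] * n_glc
        for _ in range(n_glc):
            formula = formula + LOSS_BY_FORMULA["C6H10O5"].formula
        required = _REQUIRED_CHOICES[group]
        chain += list(required[rng.integers(len(required))])

        precursor = ion_mz(formula, "+")
        mzs = []
        current = precursor
        for key in chain:
            current -= LOSS_BY_FORMULA[key].exact
            mzs.append(current)
        diag = rule_by_group[group].diagnostic_exact
        true_peaks = [(precursor, None)]  # precursor handled separately
        jittered = []
        for mz in mzs:
            jmz = mz * (1.0 + rng.normal(0.0, ppm_noise) * 1e-6)
            jittered.append(FragmentPeak(jmz, float(rng.uniform(200, 600))))
        jdiag = diag * (1.0 + rng.normal(0.0, ppm_noise) * 1e-6)
        jittered.append(FragmentPeak(jdiag, float(rng.uniform(700, 1000))))
        jprec = precursor * (1.0 + rng.normal(0.0, ppm_noise) * 1e-6)

        # spurious peaks: no catalog-consistent difference to anything
        n_spur = int(rng.binomial(len(jittered), spurious_rate))
        all_mz = [jprec] + [p.mz for p in jittered]
        spurious_mz: List[float] = []
        for _ in range(n_spur):
            for _attempt in range(200):
                cand = float(rng.uniform(80.0, jprec - 5.0))
                ok = all(
                    min(abs(abs(cand - other) - nom) for nom in nominals) > 0.7
                    for other in all_mz
                ) and all(abs(cand - d) > 0.7 for d in diag_mzs)
                if ok:
                    break
            else:  # pragma: no cover - extremely unlikely
                continue
            jittered.append(FragmentPeak(cand, float(rng.uniform(50, 150))))
            all_mz.append(cand)
            spurious_mz.append(cand)

        sid = f"syn{i:04d}"
        spectra.append(
            IonSpectrum(
                id=sid, precursor_mz=jprec, polarity="+",
                peaks=sorted(jittered, key=lambda p: p.mz),
                metadata={"series": "synthetic", "group": group,
                          "spurious_mz": tuple(spurious_mz)},
            )
        )
        truths.append(
            SpectrumTruth(
                spectrum_id=sid, group=group, ion_formula=formula.hill(),
                glucosyl_count=n_glc, hydroxy_first_step=hydroxy,
                methoxy=methoxy, loss_chain=tuple(chain),
            )
        )
    return spectra, truths


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTruth:
    """Planted structure of a synthetic expression matrix.

    ``module_sizes`` lists the planted co-expression modules;
    ``module_effects`` gives per-module log2 shifts in specific treatment
    conditions (the whole module responds, as co-regulated pathways do);
    ``baits``/``cyp_genes`` designate named genes inside planted modules.
    """

    n_genes: int = 500
    module_sizes: Tuple[Tuple[str, int], ...] = (("M1", 60), ("M2", 40))
    loading: float = 0.8
    noise_sd: float = 0.25
    base_log2: float = 5.0
    module_effects: Tuple[Tuple[str, Tuple[Tuple[str, float], ...]], ...] = ()
    gene_effects: Tuple[Tuple[str, Tuple[Tuple[str, float], ...]], ...] = ()
    baits: Tuple[Tuple[str, str], ...] = ()      # (bait id, module)
    cyp_genes: Tuple[Tuple[str, str], ...] = ()  # (gene id, module)


@dataclass
class GeneratedExpression:
    expr: pd.DataFrame                 # genes × samples, FPKM-like
    conditions: Dict[str, str]         # sample → condition
    membership: pd.Series              # gene → planted module ('none')
    annotations: pd.DataFrame          # is_cyp450 / clan / family


def gen_expression(
    truth: ExpressionTruth,
    n_samples_per_condition: int = 3,
    conditions: Sequence[str] = CONDITIONS,
    seed: int = 0,
) -> GeneratedExpression:
    """FPKM-like matrix with planted modules and treatment effects.

    log2 expression = base + loading·driver + treatment effect + noise;
    module drivers are mutually orthogonal across samples (independently
    drawn drivers can correlate strongly at a dozen samples, which would
    make planted modules genuinely inseparable).
    """
    rng = np.random.default_rng(seed)
    samples = [f"{c}T{r + 1}" for c in conditions
               for r in range(n_samples_per_condition)]
    n_samples = len(samples)
    cond_of = {s: s.rstrip("0123456789")[:-1] for s in samples}
    module_sizes = dict(truth.module_sizes)
    n_planted = sum(module_sizes.values())
    if n_planted > truth.n_genes:
        raise ValueError("module sizes exceed n_genes")
    if len(module_sizes) > n_samples:
        raise ValueError("cannot plant more orthogonal modules than samples")

    # gene naming: planted module members first, then background
    gene_ids: List[str] = []
    membership: List[str] = []
    named = {m: list() for m in module_sizes}
    for bait, module in truth.baits:
        named[module].append(bait)
    for gid, module in truth.cyp_genes:
        named[module].append(gid)
    for module, size in module_sizes.items():
        special = named[module]
        if len(special) > size:
            raise ValueError(f"module {module} too small for its named genes")
        for k in range(size):
            gene_ids.append(special[k] if k < len(special)
                            else f"{module}_g{k:04d}")
            membership.append(module)
    for k in range(truth.n_genes - n_planted):
        gene_ids.append(f"bg_g{k:05d}")
        membership.append("none")

    Q, _ = np.linalg.qr(rng.normal(size=(n_samples, len(module_sizes))))
    drivers = {m: Q[:, i] * np.sqrt(n_samples)
               for i, m in enumerate(module_sizes)}

    module_eff = {m: dict(effs) for m, effs in truth.module_effects}
    gene_eff = {g: dict(effs) for g, effs in truth.gene_effects}
    cond_idx = np.array([cond_of[s] for s in samples])

    log2x = np.empty((truth.n_genes, n_samples))
    for gi, (gid, module) in enumerate(zip(gene_ids, membership)):
        row = np.full(n_samples, truth.base_log2)
        if module != "none":
            row = row + truth.loading * drivers[module]
            for cond, eff in module_eff.get(module, {}).items():
                row = row + eff * (cond_idx == cond)
        for cond, eff in gene_eff.get(gid, {}).items():
            row = row + eff * (cond_idx == cond)
        row = row + rng.normal(0.0, truth.noise_sd, n_samples)
        log2x[gi] = row
    expr = pd.DataFrame(2.0 ** log2x - 1.0, index=gene_ids, columns=samples)
    expr[expr < 0] = 0.0

    cyp_ids = {gid for gid, _ in truth.cyp_genes}
    annotations = pd.DataFrame(
        {
            "is_cyp450": [g in cyp_ids for g in gene_ids],
            "clan": ["CYP71" if g in cyp_ids else "" for g in gene_ids],
            "family": ["CYP71" if g in cyp_ids else "" for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return GeneratedExpression(
        expr=expr, conditions=cond_of,
        membership=pd.Series(membership, index=gene_ids, name="module"),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Metabolites
# ---------------------------------------------------------------------------

def gen_metabolites(
    n_features: int,
    n_up: int,
    n_down: int,
    effect_log2: float = 1.5,
    n_per_group: int = 6,
    sigma_ln: float = 0.3,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, str], pd.Series]:
    """Two-group lognormal abundance table with planted effects.

    Returns (matrix, sample→condition map, per-feature truth labels in
    {up, down, null}).  Conditions are 'treated' vs 'control'.
    """
    if n_up + n_down > n_features:
        raise ValueError("n_up + n_down must not exceed n_features")
    rng = np.random.default_rng(seed)
    samples = [f"T{r + 1}" for r in range(n_per_group)] + \
              [f"C{r + 1}" for r in range(n_per_group)]
    conditions = {s: ("treated" if s.startswith("T") else "control")
                  for s in samples}
    labels = np.array(["up"] * n_up + ["down"] * n_down
                      + ["null"] * (n_features - n_up - n_down))
    base = rng.normal(12.0, 1.0, n_features)
    effect = np.where(labels == "up", effect_log2,
                      np.where(labels == "down", -effect_log2, 0.0))
    effect_ln = effect * np.log(2.0)
    treated = np.array([conditions[s] == "treated" for s in samples])
    noise = rng.normal(0.0, sigma_ln, (n_features, len(samples)))
    lnx = base[:, None] + effect_ln[:, None] * treated[None, :] + noise
    ids = [f"feat{i:05d}" for i in range(n_features)]
    matrix = pd.DataFrame(np.exp(lnx), index=ids, columns=samples)
    return matrix, conditions, pd.Series(labels, index=ids, name="truth")
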