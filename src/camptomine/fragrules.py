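"""Diagnostic-ion / neutral-loss rule engine for alkaloid group annotation.

A spectrum is assigned to an alkaloid series when it shows the series'
diagnostic fragment ion together with characteristic neutral losses.  The
engine builds a loss graph (edges between peaks whose mass difference
matches a catalog loss), scores each group rule by the number of satisfied
loss slots, infers substituent tags from the loss topology, and flags
compounds as novel when no same-group registry compound matches the
precursor mass.

Two matching modes are supported: ``exact_ppm`` (per-peak ppm tolerance;
an edge budgets tolerance from both of its peaks) and ``nominal``
(±0.5 Da around the integer loss mass) for printed literature values whose
decimals are not exact-mass reliable.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

from .formula import ion_mz, ppm_error
from .losses import DEFAULT_CATALOG, NeutralLoss
from .model import FragmentPeak, IonSpectrum, KnownCompoundRecord

#: Fixed tie-break order of the alkaloid groups.
GROUP_ORDER = ("CG", "PG", "SG", "VG", "VC")

#: Default per-peak fragment tolerance (ppm).  Chosen so that a peak-pair
#: difference under 5 ppm-per-peak mass jitter (σ·√2 combined) still falls
#: inside a ≥3σ window; see the methods note.
DEFAULT_FRAGMENT_TOL_PPM = 15.0

#: Default tolerance for identity matching against the known registry.
#: Identity claims are stricter than formula annotation (5 ppm).
DEFAULT_REGISTRY_TOL_PPM = 2.0


@dataclass(frozen=True)
class GroupRule:
    """One alkaloid-group rule.

    ``required`` is a tuple of slots; each slot is a frozenset of nominal
    loss masses any of which satisfies it.  ``logic`` is ``"ALL"`` (every
    slot required for the label) or ``"ANY"`` (one suffices).  The evidence
    score is always the number of satisfied slots.
    """

    group: str
    diagnostic_nominal: int
    diagnostic_exact: float
    required: Tuple[frozenset, ...]
    logic: str = "ALL"

    def __post_init__(self) -> None:
        if self.diagnostic_exact <= 0:
            raise ValueError("diagnostic m/z must be positive")
        if not self.required:
            raise ValueError("rule needs at least one required-loss slot")
        if self.logic not in ("ALL", "ANY"):
            raise ValueError(f"logic must be ALL or ANY, got {self.logic!r}")


def load_rules(path=None) -> Tuple[GroupRule, ...]:
    """Load group rules from YAML (the packaged defaults if no path)."""
    if path is None:
        text = (resources.files("camptomine") / "data" /
                "group_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    rules = []
    for entry in raw["rules"]:
        rules.append(
            GroupRule(
                group=entry["group"],
                diagnostic_nominal=int(entry["diagnostic_nominal"]),
                diagnostic_exact=float(entry["diagnostic_exact"]),
                required=tuple(frozenset(slot) for slot in entry["required"]),
                logic=str(entry.get("logic", "ALL")),
            )
        )
    return tuple(rules)


DEFAULT_RULES: Tuple[GroupRule, ...] = load_rules()


@dataclass(frozen=True)
class LossEdge:
    """A matched neutral loss between two ions of one spectrum."""

    parent_mz: float
    child_mz: float
    loss: NeutralLoss
    step_index: Optional[int]  # 1 = first cleavage from the precursor

    def __post_init__(self) -> None:
        if self.parent_mz <= self.child_mz:
            raise ValueError("loss edge must descend in m/z")


@dataclass
class ClassificationResult:
    spectrum_id: str
    labels: List[Tuple[str, int]] = field(default_factory=list)
    diagnostic_peak: Optional[FragmentPeak] = None
    matched_losses: List[LossEdge] = field(default_factory=list)
    substituent_tags: Set[str] = field(default_factory=set)
    novel: Optional[bool] = None

    @property
    def primary(self) -> Optional[str]:
        return self.labels[0][0] if self.labels else None


# ---------------------------------------------------------------------------
# Loss graph
# ---------------------------------------------------------------------------

def _match_loss(diff: float, parent: float, child: float,
                catalog: Sequence[NeutralLoss], mode: str,
                tol_ppm: float) -> Optional[NeutralLoss]:
    best: Optional[NeutralLoss] = None
    best_err = None
    for loss in catalog:
        if mode == "nominal":
            err = abs(diff - loss.nominal)
            ok = err <= 0.5
            # among equal nominals (42: propene vs ketene) prefer the
            # closer exact mass
            key = (err, abs(diff - loss.exact))
        elif mode == "exact_ppm":
            err = abs(diff - loss.exact)
            ok = err <= tol_ppm * 1e-6 * (parent + child)
            key = (err,)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if ok and (best_err is None or key < best_err):
            best, best_err = loss, key
    return best


def build_loss_graph(
    s: IonSpectrum,
    catalog: Sequence[NeutralLoss] = DEFAULT_CATALOG,
    mode: str = "exact_ppm",
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> List[LossEdge]:
    """All catalog-matching loss edges, precursor→peak and peak→peak.

    ``step_index`` is the shortest edge count from the precursor (None for
    edges whose parent is unreachable from it).
    """
    if not catalog:
        raise ValueError("loss catalog is empty")
    nodes = [s.precursor_mz] + [p.mz for p in s.peaks]
    raw: List[Tuple[int, int, NeutralLoss]] = []
    for i, parent in enumerate(nodes):
        for j, child in enumerate(nodes):
            if j == 0 or i == j or parent <= child:
                continue
            loss = _match_loss(parent - child, parent, child, catalog,
                               mode, tol_ppm)
            if loss is not None:
                raw.append((i, j, loss))
    # BFS hop counts from the precursor node
    adj: Dict[int, List[int]] = {}
    for i, j, _ in raw:
        adj.setdefault(i, []).append(j)
    dist: Dict[int, int] = {0: 0}
    queue = deque([0])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return [
        LossEdge(
            parent_mz=nodes[i], child_mz=nodes[j], loss=loss,
            step_index=dist[i] + 1 if i in dist else None,
        )
        for i, j, loss in raw
    ]


# ---------------------------------------------------------------------------
# Diagnostic ions and classification
# ---------------------------------------------------------------------------

def detect_diagnostic(
    s: IonSpectrum,
    rule: GroupRule,
    mode: str = "exact_ppm",
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> Optional[FragmentPeak]:
    """The most intense peak within tolerance of the rule's diagnostic ion."""
    if mode == "nominal":
        cands = [p for p in s.peaks
                 if abs(p.mz - rule.diagnostic_nominal) <= 0.5]
    elif mode == "exact_ppm":
        tol = tol_ppm * 1e-6 * rule.diagnostic_exact
        cands = [p for p in s.peaks
                 if abs(p.mz - rule.diagnostic_exact) <= tol]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return max(cands, key=lambda p: p.intensity, default=None)


def classify(
    s: IonSpectrum,
    rules: Sequence[GroupRule] = DEFAULT_RULES,
    catalog: Sequence[NeutralLoss] = DEFAULT_CATALOG,
    mode: str = "exact_ppm",
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> ClassificationResult:
    """Score every group rule against the spectrum's loss graph.

    A group is labeled when its diagnostic ion is present and its loss
    logic is satisfied; labels are ordered by evidence score (satisfied
    slots), then by the fixed group order CG > PG > SG > VG > VC.
    """
    graph = build_loss_graph(s, catalog, mode, tol_ppm)
    present: Set[int] = {e.loss.nominal for e in graph}
    scored: List[Tuple[str, int, FragmentPeak, List[LossEdge]]] = []
    for rule in rules:
        diag = detect_diagnostic(s, rule, mode, tol_ppm)
        if diag is None:
            continue
        satisfied = [any(n in present for n in slot) for slot in rule.required]
        score = sum(satisfied)
        labeled = all(satisfied) if rule.logic == "ALL" else score >= 1
        if not labeled:
            continue
        slot_nominals = {n for slot in rule.required for n in slot}
        evidence = [e for e in graph if e.loss.nominal in slot_nominals]
        scored.append((rule.group, score, diag, evidence))
    order = {g: i for i, g in enumerate(GROUP_ORDER)}
    scored.sort(key=lambda t: (-t[1], order.get(t[0], 99)))
    result = ClassificationResult(spectrum_id=s.id)
    result.labels = [(g, sc) for g, sc, _, _ in scored]
    if scored:
        result.diagnostic_peak = scored[0][2]
        result.matched_losses = scored[0][3]
    return result


# ---------------------------------------------------------------------------
# Substituent inference
# ---------------------------------------------------------------------------

def infer_substituents(
    s: IonSpectrum,
    result: ClassificationResult,
    graph: Sequence[LossEdge],
    rules: Sequence[GroupRule] = DEFAULT_RULES,
    mode: str = "exact_ppm",
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> ClassificationResult:
    """Attach substituent tags read off the loss-graph topology.

    glucosyl×n       n = the largest number of 162 Da (anhydroglucose)
                     edges along any single path from the precursor
    hydroxy@step1    an 18 Da (water) edge leaving the precursor
    methoxy          a 32 Da (methanol) edge within the first two steps
    hydroxylated-core a peak 16 Da above the diagnostic ion
    dehydroxy-variant the hybrid-series 56 Da slot satisfied only by 42 Da
    """
    if not result.labels:
        return result
    tags: Set[str] = set(result.substituent_tags)

    # longest 162-count over root paths (graph is a DAG: m/z decreases)
    nodes = sorted({s.precursor_mz} | {e.parent_mz for e in graph}
                   | {e.child_mz for e in graph}, reverse=True)
    best: Dict[float, int] = {s.precursor_mz: 0}
    for node in nodes:
        if node not in best:
            continue
        for e in graph:
            if e.parent_mz == node:
                cand = best[node] + (1 if e.loss.nominal == 162 else 0)
                if cand > best.get(e.child_mz, -1):
                    best[e.child_mz] = cand
    n_glc = max(best.values(), default=0)
    if n_glc:
        tags.add(f"glucosyl x{n_glc}")

    if any(e.loss.nominal == 18 and e.step_index == 1 for e in graph):
        tags.add("hydroxy@step1")
    if any(e.loss.nominal == 32 and e.step_index is not None
           and e.step_index <= 2 for e in graph):
        tags.add("methoxy")

    rule = next((r for r in rules if r.group == result.primary), None)
    if rule is not None:
        shifted = replace(rule,
                          diagnostic_nominal=rule.diagnostic_nominal + 16,
                          diagnostic_exact=rule.diagnostic_exact + 15.9949)
        if detect_diagnostic(s, shifted, mode, tol_ppm) is not None:
            tags.add("hydroxylated-core")
    if result.primary == "VC":
        nominals = {e.loss.nominal for e in graph}
        if 42 in nominals and 56 not in nominals:
            tags.add("dehydroxy-variant")
    result.substituent_tags = tags
    return result


# ---------------------------------------------------------------------------
# Novelty
# ---------------------------------------------------------------------------

def flag_novel(
    s: IonSpectrum,
    result: ClassificationResult,
    registry: Sequence[KnownCompoundRecord],
    tol_ppm: float = DEFAULT_REGISTRY_TOL_PPM,
) -> ClassificationResult:
    """novel ⇔ no same-group registry compound matches the precursor m/z.

    Isobaric compounds of a *different* group never block novelty (the
    hybrid-series isomer of a known camptothecin analog is still new).
    """
    if not result.labels:
        result.novel = None
        return result
    primary = result.primary
    for rec in registry:
        if rec.group != primary or rec.polarity != s.polarity:
            continue
        if abs(ppm_error(s.precursor_mz, rec.theoretical_mz)) <= tol_ppm:
            result.novel = False
            return result
    result.novel = True
    return result


# ---------------------------------------------------------------------------
# Batch annotation
# ---------------------------------------------------------------------------

def annotate(
    spectra: Iterable[IonSpectrum],
    registry: Sequence[KnownCompoundRecord] = (),
    rules: Sequence[GroupRule] = DEFAULT_RULES,
    catalog: Sequence[NeutralLoss] = DEFAULT_CATALOG,
    mode: str = "exact_ppm",
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    registry_tol_ppm: float = DEFAULT_REGISTRY_TOL_PPM,
) -> pd.DataFrame:
    """Classify, tag and novelty-flag a batch of spectra.

    Returns one row per spectrum: primary group, all labels with scores,
    diagnostic m/z, substituent tags, novelty and the matched loss edges.
    """
    rows = []
    for s in spectra:
        graph = build_loss_graph(s, catalog, mode, tol_ppm)
        res = classify(s, rules, catalog, mode, tol_ppm)
        res = infer_substituents(s, res, graph, rules, mode, tol_ppm)
        res = flag_novel(s, res, registry, registry_tol_ppm)
        rows.append(
            {
                "spectrum_id": s.id,
                "precursor_mz": s.precursor_mz,
                "polarity": s.polarity,
                "primary_group": res.primary,
                "labels": ";".join(f"{g}:{sc}" for g, sc in res.labels),
                "score": res.labels[0][1] if res.labels else 0,
                "diagnostic_mz": (res.diagnostic_peak.mz
                                  if res.diagnostic_peak else None),
                "tags": ";".join(sorted(res.substituent_tags)),
                "novel": res.novel,
                "n_loss_edges": len(graph),
                "evidence": ";".join(
                    f"{e.parent_mz:.4f}->{e.child_mz:.4f}({e.loss.nominal})"
                    for e in res.matched_losses),
            }
        )
    return pd.DataFrame(rows)
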