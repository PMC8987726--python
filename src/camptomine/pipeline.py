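"""End-to-end orchestration: annotate → screen → enrich → coexpress → mine.

A :class:`RunConfig` (YAML round-trippable) names every input and every
numeric parameter; :func:`run_all` executes the five stages, writes one
TSV per stage plus a manifest recording parameters, seeds, input
checksums and per-stage status.  Inputs left unset fall back to the
packaged in-study spectrum fixture and to the synthetic generators, so a
default config runs end to end with no external data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__, coexpr, diffstats, fragrules, spectra_io, synth
from .fixture import paper_fixture

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """All inputs and parameters of a full run.

    Paths set to None fall back to the packaged fixture (spectra,
    registry) or to seeded synthetic data (metabolite matrix, pathway
    sets, expression matrix, baits, annotations).
    """

    out_dir: str = "camptomine_run"
    seed: int = 1

    # annotate
    spectra_path: Optional[str] = None
    registry_path: Optional[str] = None
    match_mode: str = "nominal"
    fragment_tol_ppm: float = 15.0
    precursor_tol_ppm: float = 5.0
    registry_tol_ppm: float = 2.0

    # metabolite screen
    metabolite_matrix: Optional[str] = None
    metabolite_samples: Optional[str] = None
    condition_a: str = "treated"
    condition_b: str = "control"
    fc_high: Optional[float] = 2.0
    fc_low: Optional[float] = 0.5
    vip_min: Optional[float] = 2.0
    p_max: float = 0.05

    # enrichment
    pathways_gmt: Optional[str] = None

    # co-expression
    expression_matrix: Optional[str] = None
    expression_samples: Optional[str] = None
    soft_power: float = 8.0
    network_type: str = "unsigned"
    merge_cut_height: float = 0.25
    min_module_size: int = 30
    cut_height: float = 0.99
    kme_threshold: float = 0.75
    min_nonzero_frac: float = 0.5

    # mining
    baits_path: Optional[str] = None
    annotations_path: Optional[str] = None
    min_bait_cor: Optional[float] = None

    # synthetic fallbacks
    synth_n_metabolites: int = 300
    synth_n_up: int = 20
    synth_n_down: int = 20
    synth_effect_log2: float = 1.5
    synth_n_per_group: int = 6
    synth_n_genes: int = 600

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _read_samples(path: str) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _require(path: Optional[str], what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def _demo_expression_truth(n_genes: int) -> synth.ExpressionTruth:
    """Planted demo: three modules, baits and CYP450 candidates in the
    first one, which is upregulated by two of the three elicitors."""
    return synth.ExpressionTruth(
        n_genes=n_genes,
        module_sizes=(("M1", 80), ("M2", 60), ("M3", 50)),
        baits=(("bait_STR1", "M1"), ("bait_TDC2", "M1"), ("bait_GES", "M2")),
        cyp_genes=tuple((f"CYP_cand{k}", "M1") for k in range(6)),
        module_effects=(("M1", (("MeJa", 1.5), ("AgNO3", 1.2))),),
    )


def run_all(config: RunConfig) -> dict:
    """Execute all five stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "inputs": {},
        "stages": [],
    }

    def record(stage: str, outputs: List[str]) -> None:
        manifest["stages"].append({"stage": stage, "outputs": outputs,
                                   "status": "ok"})

    try:
        # -- 1. annotate -------------------------------------------------
        if config.spectra_path is None:
            spectra, fixture_registry = paper_fixture()
            manifest["inputs"]["spectra"] = "builtin:paper_fixture"
        else:
            p = _require(config.spectra_path, "spectra")
            spectra = spectra_io.read_mgf(p)
            fixture_registry = []
            manifest["inputs"]["spectra"] = _sha256(p)
        if config.registry_path is None:
            registry = fixture_registry or paper_fixture()[1]
            manifest["inputs"]["registry"] = "builtin:paper_fixture"
        else:
            p = _require(config.registry_path, "registry")
            registry = spectra_io.read_registry_tsv(p)
            manifest["inputs"]["registry"] = _sha256(p)
        annotated = fragrules.annotate(
            spectra, registry, mode=config.match_mode,
            tol_ppm=config.fragment_tol_ppm,
            registry_tol_ppm=config.registry_tol_ppm)
        _write(annotated, out / "annotated.tsv")
        record("annotate", ["annotated.tsv"])

        # -- 2. metabolite screen ---------------------------------------
        if config.metabolite_matrix is None:
            matrix, mcond, truth = synth.gen_metabolites(
                config.synth_n_metabolites, config.synth_n_up,
                config.synth_n_down, effect_log2=config.synth_effect_log2,
                n_per_group=config.synth_n_per_group, seed=config.seed + 1)
            manifest["inputs"]["metabolite_matrix"] = "synthetic"
            cond_a, cond_b = "treated", "control"
        else:
            p = _require(config.metabolite_matrix, "metabolite matrix")
            matrix = _read_matrix(p)
            manifest["inputs"]["metabolite_matrix"] = _sha256(p)
            sp = _require(config.metabolite_samples, "sample sheet")
            mcond = _read_samples(sp)
            truth = None
            cond_a, cond_b = config.condition_a, config.condition_b
        thresholds = diffstats.ScreenThresholds(
            fc_high=config.fc_high, fc_low=config.fc_low,
            vip_min=config.vip_min, p_max=config.p_max)
        screened = diffstats.metabolite_screen(
            matrix, mcond, cond_a, cond_b, thresholds=thresholds)
        _write(screened.rename_axis("feature"), out / "metabolite_screen.tsv",
               index=True)
        record("screen", ["metabolite_screen.tsv"])

        # -- 3. enrichment ----------------------------------------------
        if config.pathways_gmt is None:
            # demo pathway sets over the synthetic feature space
            ids = list(matrix.index)
            sets = {
                "planted_up": ids[: config.synth_n_up],
                "planted_down": ids[config.synth_n_up:
                                    config.synth_n_up + config.synth_n_down],
                "bulk": ids[config.synth_n_up + config.synth_n_down:][:100],
            }
            manifest["inputs"]["pathways"] = "synthetic"
        else:
            p = _require(config.pathways_gmt, "pathway GMT")
            sets = diffstats.read_gmt(p)
            manifest["inputs"]["pathways"] = _sha256(p)
        differential = screened.index[screened.direction != "ns"]
        enrichment = diffstats.enrich(differential, screened.index, sets)
        _write(enrichment, out / "enrichment.tsv")
        record("enrich", ["enrichment.tsv"])

        # -- 4. co-expression -------------------------------------------
        if config.expression_matrix is None:
            demo_truth = _demo_expression_truth(config.synth_n_genes)
            gen = synth.gen_expression(demo_truth, seed=config.seed + 2)
            expr, econd = gen.expr, gen.conditions
            demo_annotations = gen.annotations
            demo_baits = [b for b, _ in demo_truth.baits]
            manifest["inputs"]["expression_matrix"] = "synthetic"
        else:
            p = _require(config.expression_matrix, "expression matrix")
            expr = _read_matrix(p)
            sp = _require(config.expression_samples, "expression samples")
            econd = _read_samples(sp)
            demo_annotations, demo_baits = None, None
            manifest["inputs"]["expression_matrix"] = _sha256(p)
        filtered = coexpr.prefilter(expr, config.min_nonzero_frac)
        adj = coexpr.adjacency(filtered, power=config.soft_power,
                               kind=config.network_type)
        tom = coexpr.tom_similarity(adj)
        assignment = coexpr.detect_modules(
            tom, filtered, min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            kme_threshold=config.kme_threshold)
        assignment = coexpr.merge_modules(assignment, filtered,
                                          cut_height=config.merge_cut_height)
        _write(assignment.labels.rename_axis("gene").reset_index(),
               out / "modules.tsv")
        _write(assignment.eigengenes.rename_axis("sample"),
               out / "eigengenes.tsv", index=True)
        record("coexpress", ["modules.tsv", "eigengenes.tsv"])

        # -- 5. bait-guided mining --------------------------------------
        if config.baits_path is None:
            if demo_baits is None:
                raise FileNotFoundError(
                    "baits file required when expression data is external")
            baits = demo_baits
            annotations = demo_annotations
            manifest["inputs"]["baits"] = "synthetic"
        else:
            bp = _require(config.baits_path, "baits")
            baits = list(pd.read_csv(bp, sep="\t").iloc[:, 0].astype(str))
            ap = _require(config.annotations_path, "annotations")
            annotations = pd.read_csv(ap, sep="\t", index_col=0)
            manifest["inputs"]["baits"] = _sha256(bp)
        conditions_present = sorted(set(econd.values()))
        control = "CK" if "CK" in conditions_present else conditions_present[0]
        deg_results = {
            c: diffstats.deg_screen(filtered, econd, c, control)
            for c in conditions_present if c != control
        }
        located = coexpr.locate_baits(assignment, baits)
        _write(located, out / "bait_modules.tsv")
        candidates = coexpr.mine_candidates(
            assignment, filtered, baits, annotations,
            deg_results=deg_results, min_bait_cor=config.min_bait_cor)
        _write(candidates, out / "candidates.tsv")
        record("mine", ["bait_modules.tsv", "candidates.tsv"])
    except Exception as exc:
        manifest["stages"].append({"stage": "failed", "error": str(exc),
                                   "status": "error"})
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))
        raise

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
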