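"""Campaign orchestration: the iterative DEL-seeded screening loop.

One cycle executes, in order:

1. top-K of the current scored seed set;
2. bias (fine-tune) the generative model on that top-K;
3. sample ``n_generate`` de novo molecules;
4. score the valid unique samples;
5. take the top-K generated molecules as similarity queries;
6. expand through the purchasable catalog (union of per-query top hits,
   deduplicated, capped at ``n_catalog_hits``);
7. score the catalog hits;
8. nominate the best ``n_nominate`` purchasable compounds.

A campaign seeds cycle 1 with the catalog neighborhood of the reference
binder (the ``n_init`` most similar members, scored), then feeds each
cycle's nominations plus top catalog hits forward as the next cycle's seed
set. Every stage seed derives from the master seed by fixed offsets, so the
whole campaign is bit-reproducible and single stages can be re-run in
isolation.

Desk-scale defaults preserve the production ratios at roughly 1/100 scale
(init 2,000 / top 100 / generate 5,000 / hits 500 / nominate 50, 2 cycles).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis, catalog as catalog_mod, chem, genlm, scoring
from .chem import Molecule
from .errors import ConfigError, CycleError
from .scoring import ScoredMolecule, Stage

# Fixed stage-seed offsets (documented part of the determinism contract).
_SEED_MOD = 2**31
_OFFSET_PRETRAIN = 1
_OFFSET_BIAS = 3
_OFFSET_SAMPLE = 4


def stage_seed(master_seed: int, cycle: int, offset: int) -> int:
    """Derive a per-stage seed from the master seed and cycle number."""
    return (master_seed * 1_000_003 + cycle * 10_007 + offset) % _SEED_MOD


@dataclass(frozen=True)
class CampaignConfig:
    """All knobs of a screening campaign; validated on construction."""

    reference_smiles: str
    catalog_path: Optional[str] = None
    corpus_path: Optional[str] = None
    n_init: int = 2000
    k_top: int = 100
    n_generate: int = 5000
    n_catalog_hits: int = 500
    n_nominate: int = 50
    n_cycles: int = 2
    master_seed: int = 0
    fp_radius: int = chem.DEFAULT_RADIUS
    fp_bits: int = chem.DEFAULT_N_BITS
    w_sim: float = 10.0
    w_qed: float = 5.0
    w_size: float = 1.0
    mw_soft_cap: float = 500.0
    scorer_command: Optional[str] = None  # external adapter template, else surrogate
    w_sim_anneal: float = 1.0  # per-cycle multiplier on w_sim (<1 anneals toward diversity)
    pretrain_epochs: int = 10
    bias_epochs: int = 15
    temperature: float = 1.0
    max_len: int = 120
    per_query_hits: int = 50
    carry_forward: str = "nominations+hits"  # or "nominations"
    dedupe_across_cycles: bool = True

    def __post_init__(self) -> None:
        if self.k_top > self.n_init:
            raise ConfigError("k_top must be <= n_init")
        if self.n_nominate > self.n_catalog_hits:
            raise ConfigError("n_nominate must be <= n_catalog_hits")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.carry_forward not in ("nominations+hits", "nominations"):
            raise ConfigError(f"unknown carry_forward mode {self.carry_forward!r}")

    @property
    def fp_config(self) -> catalog_mod.FpConfig:
        return catalog_mod.FpConfig(radius=self.fp_radius, n_bits=self.fp_bits)


@dataclass
class CampaignState:
    """What flows between cycles: the model, the scored seed set, provenance."""

    model: genlm.GenerativeModel
    seed_set: list[ScoredMolecule]
    nominated_ids: set = field(default_factory=set)


@dataclass
class CycleReport:
    """All stage sets of one cycle with summary statistics."""

    cycle: int
    seeds: list[ScoredMolecule]
    top_seeds: list[ScoredMolecule]
    generated: list[ScoredMolecule]
    top_generated: list[ScoredMolecule]
    catalog_hits: list[ScoredMolecule]
    nominations: list[ScoredMolecule]
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage_name, items in (
            ("seed", self.seeds),
            ("top_seed", self.top_seeds),
            ("generated", self.generated),
            ("top_generated", self.top_generated),
            ("catalog_hit", self.catalog_hits),
            ("nomination", self.nominations),
        ):
            for rank, sm in enumerate(items, start=1):
                rows.append(
                    {
                        "cycle": self.cycle,
                        "stage": stage_name,
                        "rank": rank,
                        "id": sm.molecule.source_id,
                        "smiles": sm.molecule.smiles_canonical,
                        "score": sm.score,
                    }
                )
        return pd.DataFrame(rows)


def _summary_stats(items: Sequence[ScoredMolecule]) -> dict:
    finite = [s.score for s in items if not s.failed]
    return {
        "n": len(items),
        "mean_score": float(np.mean(finite)) if finite else None,
        "best_score": float(np.min(finite)) if finite else None,
    }


def _make_scorer(
    config: CampaignConfig, reference: Molecule, cycle: int = 1
) -> scoring.Scorer:
    """Scorer for a given cycle; the similarity weight anneals geometrically."""
    if config.scorer_command:
        return scoring.external_scorer_adapter(config.scorer_command)
    target = scoring.SurrogateTarget(
        reference_fp=chem.fingerprint(reference, config.fp_radius, config.fp_bits),
        w_sim=config.w_sim * config.w_sim_anneal ** max(0, cycle - 1),
        w_qed=config.w_qed,
        w_size=config.w_size,
        mw_soft_cap=config.mw_soft_cap,
    )
    return scoring.SurrogateScorer(target)


def run_cycle(
    config: CampaignConfig,
    state: CampaignState,
    index: catalog_mod.CatalogIndex,
    cycle: int,
    scorer: Optional[scoring.Scorer] = None,
    reference: Optional[Molecule] = None,
) -> tuple[CycleReport, CampaignState]:
    """Execute one bias -> generate -> expand -> nominate cycle."""
    reference = reference or chem.canonicalize(config.reference_smiles)
    scorer = scorer or _make_scorer(config, reference, cycle)

    top_seeds = scoring.top_k(state.seed_set, config.k_top)
    if not top_seeds:
        raise CycleError(f"cycle {cycle}: empty seed set after failure filtering")

    biased = genlm.bias(
        state.model,
        top_seeds,
        epochs=config.bias_epochs,
        seed=stage_seed(config.master_seed, cycle, _OFFSET_BIAS),
    )
    mols, stats = genlm.sample_with_stats(
        biased,
        n=config.n_generate,
        seed=stage_seed(config.master_seed, cycle, _OFFSET_SAMPLE),
        max_len=config.max_len,
        temperature=config.temperature,
    )
    if not mols:
        raise CycleError(
            f"cycle {cycle}: no valid samples out of {config.n_generate}; "
            "increase pretraining epochs or relax generation settings"
        )
    generated = scoring.score_batch(mols, scorer, Stage.GENERATED, cycle)
    top_generated = scoring.top_k(generated, config.k_top)

    queries = [
        chem.fingerprint(sm.molecule, config.fp_radius, config.fp_bits)
        for sm in top_generated
    ]
    hits = catalog_mod.batch_search_union(
        index, queries, per_query_n=config.per_query_hits, max_total=config.n_catalog_hits
    )
    if config.dedupe_across_cycles:
        hits = [(i, s) for i, s in hits if i not in state.nominated_ids]
    hit_ids = [i for i, _ in hits]
    hit_mols = [
        chem.canonicalize(smi, source_id=i)
        for i, smi in zip(hit_ids, catalog_mod.smiles_of(index, hit_ids))
    ]
    catalog_hits = scoring.score_batch(hit_mols, scorer, Stage.CATALOG_HIT, cycle)
    nominations_raw = scoring.top_k(catalog_hits, config.n_nominate)
    nominations = [
        ScoredMolecule(molecule=sm.molecule, score=sm.score, stage=Stage.NOMINATION,
                       cycle=cycle)
        for sm in nominations_raw
    ]
    if not nominations:
        raise CycleError(f"cycle {cycle}: no catalog hits survived scoring")

    nom_sims, nom_max = analysis.novelty_profile(
        [sm.molecule for sm in nominations], reference, config.fp_radius, config.fp_bits
    )
    report = CycleReport(
        cycle=cycle,
        seeds=list(state.seed_set),
        top_seeds=top_seeds,
        generated=generated,
        top_generated=top_generated,
        catalog_hits=catalog_hits,
        nominations=nominations,
        summary={
            "cycle": cycle,
            "validity_rate": stats["validity_rate"],
            "n_unique_generated": stats["n_unique"],
            "stages": {
                "seed": _summary_stats(state.seed_set),
                "generated": _summary_stats(generated),
                "catalog_hit": _summary_stats(catalog_hits),
                "nomination": _summary_stats(nominations),
            },
            "max_tanimoto_to_reference": nom_max,
            "mean_tanimoto_to_reference": float(nom_sims.mean()),
        },
    )
    if config.carry_forward == "nominations+hits":
        carry = {sm.molecule.smiles_canonical: sm for sm in catalog_hits if not sm.failed}
        for sm in nominations:
            carry[sm.molecule.smiles_canonical] = sm
        next_seed = list(carry.values())
    else:
        next_seed = list(nominations)
    new_state = CampaignState(
        model=biased,
        seed_set=next_seed,
        nominated_ids=state.nominated_ids | {sm.molecule.source_id for sm in nominations},
    )
    return report, new_state


def run_campaign(
    config: CampaignConfig,
    outdir: Optional[Path] = None,
    model: Optional[genlm.GenerativeModel] = None,
    index: Optional[catalog_mod.CatalogIndex] = None,
    catalog_records: Optional[Sequence[tuple[str, str]]] = None,
    corpus: Optional[Sequence[str]] = None,
) -> list[CycleReport]:
    """Run a full campaign: initialize, then fold ``run_cycle`` n_cycles times.

    Inputs may come from paths in the config or be passed in memory (an
    already-built index, a pretrained model, a corpus list) — useful when
    sharing one pretrained model across several master seeds. With the
    surrogate scorer the result is a pure function of (config, inputs).
    """
    reference = chem.canonicalize(config.reference_smiles)

    if index is None:
        if catalog_records is None:
            if config.catalog_path is None:
                raise ConfigError("need catalog_path, catalog_records, or index")
            catalog_records = _read_catalog(config.catalog_path)
        index = catalog_mod.build_index(catalog_records, config.fp_config)
    if index.fp_config != config.fp_config:
        raise ConfigError("index fingerprint config differs from campaign config")

    if model is None:
        if corpus is None:
            if config.corpus_path is None:
                raise ConfigError("need corpus_path, corpus, or model")
            corpus = [smi for _id, smi in _read_catalog(config.corpus_path)]
        model = genlm.pretrain(
            corpus,
            epochs=config.pretrain_epochs,
            seed=stage_seed(config.master_seed, 0, _OFFSET_PRETRAIN),
        )

    init_scorer = _make_scorer(config, reference, cycle=1)
    init_hits = catalog_mod.init_seed_set(index, reference, config.n_init)
    init_ids = [i for i, _ in init_hits]
    init_mols = [
        chem.canonicalize(smi, source_id=i)
        for i, smi in zip(init_ids, catalog_mod.smiles_of(index, init_ids))
    ]
    seed_set = scoring.score_batch(init_mols, init_scorer, Stage.INIT, 0)
    state = CampaignState(model=model, seed_set=seed_set)

    reports: list[CycleReport] = []
    try:
        for cycle in range(1, config.n_cycles + 1):
            report, state = run_cycle(
                config, state, index, cycle,
                scorer=_make_scorer(config, reference, cycle),
                reference=reference,
            )
            reports.append(report)
    finally:
        if outdir is not None:
            _write_outputs(config, reports, outdir)
    return reports


def _read_catalog(path) -> list[tuple[str, str]]:
    path = Path(path)
    if path.suffix.lower() == ".smi":
        return chem.read_smi(path)
    df = pd.read_csv(path)
    if not {"id", "smiles"} <= set(df.columns):
        raise ConfigError(f"{path}: CSV catalog needs id,smiles columns")
    return list(zip(df["id"].astype(str), df["smiles"].astype(str)))


def config_hash(config: CampaignConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_outputs(config: CampaignConfig, reports: list[CycleReport], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for report in reports:
        report.to_frame().to_csv(outdir / f"cycle{report.cycle}_stages.csv", index=False)
    import rdkit

    from . import __version__

    manifest = {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "master_seed": config.master_seed,
        "stage_seeds": {
            f"cycle{c}": {
                "bias": stage_seed(config.master_seed, c, _OFFSET_BIAS),
                "sample": stage_seed(config.master_seed, c, _OFFSET_SAMPLE),
            }
            for c in range(1, config.n_cycles + 1)
        },
        "pretrain_seed": stage_seed(config.master_seed, 0, _OFFSET_PRETRAIN),
        "n_cycles_completed": len(reports),
        "summaries": [r.summary for r in reports],
        "versions": {
            "delgem": __version__,
            "numpy": np.__version__,
            "rdkit": rdkit.__version__,
            "python": platform.python_version(),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
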