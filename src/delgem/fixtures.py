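"""Synthetic-data generators: catalog, DEL counts, and dose-response curves.

Every generator is a pure function of its spec (seed included), so fixtures
regenerate bit-identically and every downstream test is a recovery test
against an emitted truth table.

The catalog generator assembles molecules from a frozen fragment grammar
(ring cores with two attachment points, linkers, caps) via RDKit ``molzip``,
guaranteeing chemical validity by construction and giving controllable
similarity structure. A subset of "planted actives" is built by decorating
the reference scaffold so their Tanimoto similarity to the reference falls
inside a configurable band — similar enough to be reachable by catalog
similarity expansion, distinct enough to exercise novelty metrics.

DEL counts emulate replicate selections of a barcoded library: background
reads are Poisson with a mean of ~20 reads per member per replicate, and
planted binders are Poisson with that mean multiplied by an enrichment
factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem
from .analysis import DoseResponse
from .errors import FixtureError

# --------------------------------------------------------------------------
# Frozen fragment grammar. Cores carry attachment maps 1 and 2, linkers
# maps 2 and 3, caps a single map. All combinations zip into valid SMILES.
# --------------------------------------------------------------------------

CORES = (
    "c1cc([*:1])cc([*:2])c1",       # benzene-1,3
    "c1cc([*:1])ccc1[*:2]",         # benzene-1,4
    "c1nc([*:1])ccc1[*:2]",         # pyridine
    "c1cc([*:1])cnc1[*:2]",         # pyridine isomer
    "c1cc([*:1])sc1[*:2]",          # thiophene
    "c1oc([*:1])cc1[*:2]",          # furan
    "c1cc2cc([*:1])ccc2cc1[*:2]",   # naphthalene
    "C1CN([*:1])CCN1[*:2]",         # piperazine
    "C1CN([*:1])CCC1[*:2]",         # piperidine
    "C1CC([*:1])CCC1[*:2]",         # cyclohexane
    "c1nc([*:1])ncc1[*:2]",         # pyrimidine
    "c1cc([*:1])n([*:2])c1",        # N-substituted pyrrole
)

LINKERS = (
    "[*:2]C(=O)N[*:3]",             # amide
    "[*:2]NC(=O)[*:3]",             # reverse amide
    "[*:2]C(=O)[*:3]",              # ketone
    "[*:2]S(=O)(=O)N[*:3]",         # sulfonamide
    "[*:2]CC[*:3]",                 # ethylene
    "[*:2]C[*:3]",                  # methylene
    "[*:2]OC[*:3]",                 # oxymethylene
    "[*:2]CN[*:3]",                 # aminomethylene
    None,                           # direct cap on the core's second point
)

CAPS = (
    "C[*:{m}]",                     # methyl
    "CC[*:{m}]",                    # ethyl
    "CC(C)[*:{m}]",                 # isopropyl
    "FC(F)(F)[*:{m}]",              # trifluoromethyl
    "CO[*:{m}]",                    # methoxy
    "OC[*:{m}]",                    # hydroxymethyl
    "N#C[*:{m}]",                   # nitrile
    "CN(C)[*:{m}]",                 # dimethylamino
    "C1CC1[*:{m}]",                 # cyclopropyl
    "c1ccccc1[*:{m}]",              # phenyl
    "c1ccncc1[*:{m}]",              # pyridyl
    "CN1CCN(CC1)[*:{m}]",           # 4-methylpiperazin-1-yl
    "C1CCOC1[*:{m}]",               # tetrahydrofuranyl
    "CC(=O)N[*:{m}]",               # acetamido
    "CS(=O)(=O)[*:{m}]",            # methylsulfonyl
    "OCC[*:{m}]",                   # hydroxyethyl
)

#: Stand-in reference binder: a methyl-piperazine amide scaffold of the kind
#: recognized by methyl-lysine reader pockets. Built from the same chemistry
#: as the grammar so planted actives can decorate it.
REFERENCE_SMILES = "CN1CCN(CC1)C(=O)c1ccc(OCc2ccccc2)cc1"

#: Reference scaffold with one open attachment point, used to plant actives.
_REFERENCE_SCAFFOLD = "CN1CCN(CC1)C(=O)c1ccc([*:2])cc1"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 0
    catalog_size: int = 2000
    n_planted: int = 50
    planted_similarity_band: tuple[float, float] = (0.35, 0.6)
    del_library_size: int = 1000
    del_replicates: int = 2
    del_enrichment_factor: float = 10.0
    del_mean_reads: float = 20.0

    def __post_init__(self) -> None:
        lo, hi = self.planted_similarity_band
        if not (0.0 <= lo < hi <= 1.0):
            raise FixtureError(f"invalid similarity band {self.planted_similarity_band}")
        if self.catalog_size < self.n_planted:
            raise FixtureError("catalog_size must be >= n_planted")
        if self.del_library_size < self.n_planted:
            raise FixtureError("del_library_size must be >= n_planted")


def _zip_fragments(*frag_smiles: str) -> str | None:
    """Assemble mapped fragments into one molecule; None if assembly fails."""
    mols = [Chem.MolFromSmiles(s) for s in frag_smiles]
    if any(m is None for m in mols):
        return None
    combo = reduce(Chem.CombineMols, mols)
    try:
        zipped = Chem.molzip(combo)
        Chem.SanitizeMol(zipped)
    except Exception:
        return None
    return Chem.MolToSmiles(zipped)


def _random_grammar_smiles(rng: np.random.Generator) -> str | None:
    """One random core(+linker)+caps assembly; canonical SMILES or None."""
    core = CORES[rng.integers(len(CORES))]
    cap_a = CAPS[rng.integers(len(CAPS))].format(m=1)
    linker = LINKERS[rng.integers(len(LINKERS))]
    cap_b_t = CAPS[rng.integers(len(CAPS))]
    if linker is None:
        return _zip_fragments(core, cap_a, cap_b_t.format(m=2))
    return _zip_fragments(core, cap_a, linker, cap_b_t.format(m=3))


def make_corpus(n: int, seed: int) -> list[str]:
    """Drug-like SMILES corpus for language-model pretraining.

    Returns ``n`` unique canonical SMILES drawn from the fragment grammar.
    """
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise FixtureError(f"grammar exhausted after {attempts} attempts for n={n}")
        smi = _random_grammar_smiles(rng)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
    return out


def _remap(frag: str, mapping: dict[int, int]) -> str:
    """Renumber attachment maps in a fragment SMILES (e.g. [*:2] -> [*:3])."""
    out = frag
    for src, dst in mapping.items():  # two-phase to survive chained renames
        out = out.replace(f"[*:{src}]", f"<<{dst}>>")
    for dst in mapping.values():
        out = out.replace(f"<<{dst}>>", f"[*:{dst}]")
    return out


def _decorate_reference(rng: np.random.Generator) -> str | None:
    """One random decoration of the reference scaffold: a cap joined by
    zero, one, or two linkers (longer chains widen the similarity range)."""
    n_linkers = int(rng.integers(0, 3))
    cap = CAPS[rng.integers(len(CAPS))]
    real_linkers = [l for l in LINKERS if l is not None]
    if n_linkers == 0:
        return _zip_fragments(_REFERENCE_SCAFFOLD, cap.format(m=2))
    if n_linkers == 1:
        linker = real_linkers[rng.integers(len(real_linkers))]
        return _zip_fragments(_REFERENCE_SCAFFOLD, linker, cap.format(m=3))
    l1 = real_linkers[rng.integers(len(real_linkers))]
    l2 = _remap(real_linkers[rng.integers(len(real_linkers))], {2: 3, 3: 4})
    return _zip_fragments(_REFERENCE_SCAFFOLD, l1, l2, cap.format(m=4))


def _planted_actives(spec: FixtureSpec, rng: np.random.Generator,
                     fp_radius: int, fp_bits: int) -> list[str]:
    """Decorate the reference scaffold until n_planted fall in the band."""
    ref_fp = chem.fingerprint(chem.canonicalize(REFERENCE_SMILES), fp_radius, fp_bits)
    lo, hi = spec.planted_similarity_band
    planted: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 100 * max(spec.n_planted, 1)
    while len(planted) < spec.n_planted:
        attempts += 1
        if attempts > max_attempts:
            raise FixtureError(
                f"could not plant {spec.n_planted} actives in band [{lo}, {hi}] "
                f"after {attempts} attempts"
            )
        smi = _decorate_reference(rng)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        sim = chem.tanimoto(chem.fingerprint(chem.canonicalize(smi), fp_radius, fp_bits), ref_fp)
        if lo <= sim <= hi:
            planted.append(smi)
    return planted


def make_catalog(
    spec: FixtureSpec,
    fp_radius: int = chem.DEFAULT_RADIUS,
    fp_bits: int = chem.DEFAULT_N_BITS,
) -> tuple[list[tuple[str, str]], dict]:
    """Synthetic purchasable catalog with planted high-similarity actives.

    Returns ``(records, truth)`` where records are (id, smiles) pairs of
    ``spec.catalog_size`` unique valid molecules and ``truth`` maps
    ``"planted_ids"`` to the ids decorating the reference scaffold inside
    ``spec.planted_similarity_band`` and ``"reference_smiles"`` to the
    reference binder.
    """
    rng = np.random.default_rng(spec.seed)
    planted = _planted_actives(spec, rng, fp_radius, fp_bits)
    background: list[str] = []
    seen = set(planted)
    attempts = 0
    n_background = spec.catalog_size - len(planted)
    while len(background) < n_background:
        attempts += 1
        if attempts > 200 * max(n_background, 1):
            raise FixtureError("grammar exhausted while generating catalog background")
        smi = _random_grammar_smiles(rng)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        background.append(smi)
    all_smiles = planted + background
    order = rng.permutation(len(all_smiles))
    width = max(6, len(str(spec.catalog_size)))
    records, planted_ids = [], []
    for pos, orig in enumerate(order):
        ident = f"CAT{pos:0{width}d}"
        records.append((ident, all_smiles[orig]))
        if orig < len(planted):
            planted_ids.append(ident)
    truth = {
        "planted_ids": sorted(planted_ids),
        "reference_smiles": REFERENCE_SMILES,
        "band": list(spec.planted_similarity_band),
    }
    return records, truth


def make_del_counts(
    spec: FixtureSpec, planted_ids: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Replicate DEL selection counts with planted enriched members.

    Background counts are Poisson(``del_mean_reads``) per replicate; rows in
    ``planted_ids`` are Poisson(``del_mean_reads * del_enrichment_factor``).
    If ``planted_ids`` is None, ``spec.n_planted`` members are chosen at
    random. Returns the count table (member_id, count_rep1..R) and the
    planted ids.
    """
    rng = np.random.default_rng(spec.seed + 1)
    width = max(6, len(str(spec.del_library_size)))
    member_ids = [f"DEL{i:0{width}d}" for i in range(spec.del_library_size)]
    if planted_ids is None:
        chosen = rng.choice(spec.del_library_size, size=spec.n_planted, replace=False)
        planted_ids = sorted(member_ids[i] for i in chosen)
    planted_set = set(planted_ids)
    lam = np.full(spec.del_library_size, spec.del_mean_reads)
    for i, mid in enumerate(member_ids):
        if mid in planted_set:
            lam[i] = spec.del_mean_reads * spec.del_enrichment_factor
    counts = rng.poisson(lam[:, None], size=(spec.del_library_size, spec.del_replicates))
    df = pd.DataFrame({"member_id": member_ids})
    for r in range(spec.del_replicates):
        df[f"count_rep{r + 1}"] = counts[:, r]
    return df, planted_ids


def make_dose_response(
    ic50_uM: float,
    hill: float = 1.0,
    noise_sd: float = 0.05,
    n_points: int = 8,
    n_replicates: int = 3,
    seed: int = 0,
    bottom: float = 0.0,
    top: float = 1.0,
    decades: float = 2.0,
) -> list[DoseResponse]:
    """Noisy four-parameter-logistic curves on a log dilution series.

    Concentrations span ``decades`` log10 units either side of the true
    IC50. ``noise_sd`` is a coefficient of variation: each response is
    multiplied by ``1 + N(0, noise_sd)``, matching how plate-reader signal
    noise scales with signal intensity. One :class:`DoseResponse` per
    replicate.
    """
    if n_points < 5:
        raise FixtureError(f"need >= 5 concentration points, got {n_points}")
    rng = np.random.default_rng(seed)
    conc = np.logspace(np.log10(ic50_uM) - decades, np.log10(ic50_uM) + decades, n_points)
    curves = []
    for rep in range(n_replicates):
        ideal = bottom + (top - bottom) / (1.0 + (conc / ic50_uM) ** hill)
        resp = ideal * (1.0 + rng.normal(0.0, noise_sd, size=n_points))
        curves.append(
            DoseResponse(
                concentrations_uM=conc.copy(),
                responses=resp,
                replicate_id=f"rep{rep + 1}",
            )
        )
    return curves


def write_catalog_smi(path, records) -> None:
    chem.write_smi(path, records)


def write_del_counts_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
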