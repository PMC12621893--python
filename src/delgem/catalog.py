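"""Purchasable-catalog fingerprint index with exact pruned Tanimoto search.

The index stores packed binary fingerprints (one row per catalog member)
plus per-row popcounts. Top-N search uses the Swamidass-Baldi popcount
bound: for a query with popcount q and a row with popcount p, the Tanimoto
similarity can never exceed min(p, q) / max(p, q), so rows are visited in
decreasing bound order and scanning stops as soon as the bound falls below
the current N-th best similarity. Results are identical to an exhaustive
scan — the bound only prunes rows that cannot enter the top N.

Ties in similarity break by id lexicographic ascending, making every search
deterministic and independent of catalog row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import chem
from .chem import Fingerprint, Molecule
from .errors import ConfigError, DimensionError, DuplicateIdError


@dataclass(frozen=True)
class FpConfig:
    radius: int = chem.DEFAULT_RADIUS
    n_bits: int = chem.DEFAULT_N_BITS


@dataclass
class CatalogIndex:
    """Immutable fingerprint index over a purchasable catalog."""

    ids: np.ndarray          # unicode array, one id per row
    smiles: np.ndarray       # canonical SMILES per row
    packed: np.ndarray       # uint8 matrix (n_rows, n_bits // 8)
    popcounts: np.ndarray    # int32 per row
    fp_config: FpConfig
    n_skipped: int = 0       # unparsable input rows dropped during build

    def __len__(self) -> int:
        return len(self.ids)

    def member_fingerprint(self, row: int) -> Fingerprint:
        return Fingerprint(
            packed=self.packed[row], n_bits=self.fp_config.n_bits,
            radius=self.fp_config.radius,
        )


def build_index(
    catalog: Iterable[tuple[str, str]], fp_config: FpConfig = FpConfig()
) -> CatalogIndex:
    """Build an index from an (id, smiles) stream.

    Unparsable SMILES are counted and skipped with a warning; a repeated id
    raises :class:`DuplicateIdError` naming it. Rebuilding from the same
    input is bit-identical.
    """
    ids: list[str] = []
    smiles: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    n_skipped = 0
    for ident, smi in catalog:
        if ident in seen:
            raise DuplicateIdError(f"duplicate catalog id: {ident!r}")
        seen.add(ident)
        try:
            mol = chem.canonicalize(smi, source_id=ident)
        except chem.ParseError:
            n_skipped += 1
            continue
        fp = chem.fingerprint(mol, fp_config.radius, fp_config.n_bits)
        ids.append(ident)
        smiles.append(mol.smiles_canonical)
        rows.append(fp.packed)
    if n_skipped:
        warnings.warn(f"build_index skipped {n_skipped} unparsable rows", stacklevel=2)
    n_bytes = fp_config.n_bits // 8
    packed = (
        np.vstack(rows) if rows else np.empty((0, n_bytes), dtype=np.uint8)
    )
    popcounts = np.bitwise_count(packed).sum(axis=1).astype(np.int32)
    return CatalogIndex(
        ids=np.array(ids, dtype=object),
        smiles=np.array(smiles, dtype=object),
        packed=packed,
        popcounts=popcounts,
        fp_config=fp_config,
        n_skipped=n_skipped,
    )


def save_index(index: CatalogIndex, path) -> None:
    """Persist as a single .npz file (header config + packed rows)."""
    np.savez_compressed(
        path,
        ids=index.ids.astype(str),
        smiles=index.smiles.astype(str),
        packed=index.packed,
        popcounts=index.popcounts,
        radius=np.int64(index.fp_config.radius),
        n_bits=np.int64(index.fp_config.n_bits),
        n_skipped=np.int64(index.n_skipped),
    )


def load_index(path) -> CatalogIndex:
    with np.load(path, allow_pickle=False) as z:
        return CatalogIndex(
            ids=z["ids"].astype(object),
            smiles=z["smiles"].astype(object),
            packed=np.ascontiguousarray(z["packed"], dtype=np.uint8),
            popcounts=z["popcounts"].astype(np.int32),
            fp_config=FpConfig(radius=int(z["radius"]), n_bits=int(z["n_bits"])),
            n_skipped=int(z["n_skipped"]),
        )


def _tanimoto_rows(index: CatalogIndex, rows: np.ndarray, query: Fingerprint) -> np.ndarray:
    """Vectorized Tanimoto of the query against a subset of index rows."""
    inter = np.bitwise_count(index.packed[rows] & query.packed).sum(axis=1)
    q = query.popcount
    union = index.popcounts[rows] + q - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(union > 0, inter / union, 0.0)
    return sims


def search(
    index: CatalogIndex, query: Fingerprint, top_n: int, _chunk: int = 8192
) -> list[tuple[str, float]]:
    """Exact top-N Tanimoto search with popcount-bound pruning.

    Returns at most ``top_n`` (id, similarity) pairs sorted by similarity
    descending, ties by id ascending. Identical to an exhaustive scan.
    """
    if query.n_bits != index.fp_config.n_bits:
        raise DimensionError(
            f"query width {query.n_bits} != index width {index.fp_config.n_bits}"
        )
    if top_n < 0:
        raise ConfigError(f"top_n must be >= 0, got {top_n}")
    n = len(index)
    if top_n == 0 or n == 0:
        return []
    q = query.popcount
    p = index.popcounts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        bounds = np.where(
            np.maximum(p, q) > 0, np.minimum(p, q) / np.maximum(p, q), 1.0
        )  # two empty fingerprints have similarity 0 but bound handling is moot
    order = np.argsort(-bounds, kind="stable")
    best_sims: list[float] = []
    best_rows: list[int] = []
    threshold = -1.0
    for start in range(0, n, _chunk):
        block = order[start : start + _chunk]
        if len(best_sims) >= top_n and bounds[block[0]] < threshold:
            break  # no remaining row can beat the current N-th best
        sims = _tanimoto_rows(index, block, query)
        best_sims.extend(sims.tolist())
        best_rows.extend(block.tolist())
        if len(best_sims) >= top_n:
            kth = np.partition(np.array(best_sims), -top_n)[-top_n]
            threshold = float(kth)
    sims_arr = np.array(best_sims)
    rows_arr = np.array(best_rows)
    # final exact ranking with deterministic tie-break by id
    keys = sorted(
        range(len(sims_arr)), key=lambda i: (-sims_arr[i], index.ids[rows_arr[i]])
    )[:top_n]
    return [(str(index.ids[rows_arr[i]]), float(sims_arr[i])) for i in keys]


def init_seed_set(
    index: CatalogIndex, reference: Molecule, m: int
) -> list[tuple[str, float]]:
    """The m catalog members most similar to the reference compound.

    This is the campaign initialization step: the seed pool is the
    similarity neighborhood of the known binder, not a diverse set.
    """
    if m < 1:
        raise ConfigError(f"m must be >= 1, got {m}")
    fp = chem.fingerprint(reference, index.fp_config.radius, index.fp_config.n_bits)
    return search(index, fp, m)


def batch_search_union(
    index: CatalogIndex,
    queries: Sequence[Fingerprint],
    per_query_n: int,
    max_total: int,
) -> list[tuple[str, float]]:
    """Union of per-query top-N hits, deduplicated keeping each id's maximum
    similarity, truncated to ``max_total`` (similarity desc, id asc)."""
    best: dict[str, float] = {}
    for fp in queries:
        for ident, sim in search(index, fp, per_query_n):
            if sim > best.get(ident, -1.0):
                best[ident] = sim
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:max_total]


def smiles_of(index: CatalogIndex, ids: Sequence[str]) -> list[str]:
    """Canonical SMILES for catalog ids (raises KeyError on unknown id)."""
    lookup = {str(i): s for i, s in zip(index.ids, index.smiles)}
    return [lookup[str(i)] for i in ids]
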