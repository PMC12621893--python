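"""Pluggable structure-based scoring: surrogate scorer and external adapter.

Scores follow the docking convention: lower is better, and all rank
operations sort ascending. A scorer is any callable mapping a list of
molecules to a list of floats of the same length; per-molecule failures are
reported as ``+inf`` so they survive batch bookkeeping but never enter a
top-K selection.

The surrogate scorer replaces commercial docking at desk scale. It rewards
fingerprint similarity to the reference binder and drug-likeness, and
softly penalizes molecular weight above a cap:

    score = -(w_sim * T(fp(mol), fp(ref)) + w_qed * QED(mol))
            + w_size * max(0, MW - mw_soft_cap) / 100

The similarity/drug-likeness coupling is deliberate: it makes the
pipeline-level properties (score improvement under generative biasing,
reachability of planted catalog neighborhoods) exercisable without any 3-D
structure code. An external docking program plugs in through
:func:`external_scorer_adapter` with a .smi/CSV file exchange.
"""

from __future__ import annotations

import csv
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Optional, Sequence

from . import chem
from .chem import Fingerprint, Molecule
from .errors import AdapterError, ConfigError

#: Scorer contract: molecules in, one float per molecule out (lower better).
Scorer = Callable[[Sequence[Molecule]], list[float]]

FAILURE_SCORE = math.inf


class Stage(str, Enum):
    INIT = "init"
    GENERATED = "generated"
    CATALOG_HIT = "catalog_hit"
    NOMINATION = "nomination"


@dataclass(frozen=True)
class ScoredMolecule:
    molecule: Molecule
    score: float
    stage: Stage
    cycle: int

    @property
    def failed(self) -> bool:
        return not math.isfinite(self.score)


@dataclass(frozen=True)
class SurrogateTarget:
    """Parameters of the surrogate objective (stands in for a receptor grid)."""

    reference_fp: Fingerprint
    w_sim: float = 10.0
    w_qed: float = 5.0
    w_size: float = 1.0
    mw_soft_cap: float = 500.0

    def __post_init__(self) -> None:
        if min(self.w_sim, self.w_qed, self.w_size) < 0:
            raise ConfigError("surrogate weights must be >= 0")


def surrogate_score(mol: Molecule, target: SurrogateTarget) -> float:
    """Deterministic surrogate docking score of one molecule (lower better)."""
    fp = chem.fingerprint(
        mol, radius=target.reference_fp.radius, n_bits=target.reference_fp.n_bits
    )
    sim = chem.tanimoto(fp, target.reference_fp)
    panel = chem.property_panel(mol)
    size_penalty = max(0.0, panel.mw - target.mw_soft_cap) / 100.0
    return -(target.w_sim * sim + target.w_qed * panel.qed) + target.w_size * size_penalty


class SurrogateScorer:
    """Scorer-contract wrapper around :func:`surrogate_score`."""

    def __init__(self, target: SurrogateTarget):
        self.target = target

    def __call__(self, mols: Sequence[Molecule]) -> list[float]:
        out = []
        for m in mols:
            try:
                out.append(surrogate_score(m, self.target))
            except Exception:
                out.append(FAILURE_SCORE)
        return out


def score_batch(
    mols: Sequence[Molecule], scorer: Scorer, stage: Stage, cycle: int
) -> list[ScoredMolecule]:
    """Score a batch, preserving order; failures carry the ``+inf`` sentinel."""
    raw = scorer(mols)
    if len(raw) != len(mols):
        raise AdapterError(
            f"scorer returned {len(raw)} scores for {len(mols)} molecules"
        )
    out = []
    for mol, s in zip(mols, raw):
        score = float(s) if s is not None and math.isfinite(float(s)) else FAILURE_SCORE
        out.append(ScoredMolecule(molecule=mol, score=score, stage=stage, cycle=cycle))
    return out


def top_k(scored: Sequence[ScoredMolecule], k: int) -> list[ScoredMolecule]:
    """Best k by ascending score, failures excluded; ties by canonical SMILES."""
    ok = [s for s in scored if not s.failed]
    ranked = sorted(ok, key=lambda s: (s.score, s.molecule.smiles_canonical))
    return ranked[:k]


def external_scorer_adapter(
    command_template: str, workdir: Optional[Path] = None
) -> Scorer:
    """Wrap an external scoring executable as a scorer-contract callable.

    Exchange format: molecules are written to an input ``.smi`` file
    (``SMILES ID`` per line, ids ``m0..mN-1``); the command template is
    formatted with ``{input}`` and ``{output}`` placeholders and executed;
    the output CSV must contain ``id,score`` rows. Molecules the executable
    omits get the ``+inf`` sentinel. A nonzero exit status, a missing
    executable, or a malformed score file raises :class:`AdapterError`.
    """
    if "{input}" not in command_template or "{output}" not in command_template:
        raise ConfigError("command template must contain {input} and {output}")
    exe = command_template.split()[0]
    if shutil.which(exe) is None and not Path(exe).exists():
        raise AdapterError(f"external scorer executable not found: {exe!r}")

    def scorer(mols: Sequence[Molecule]) -> list[float]:
        with tempfile.TemporaryDirectory(dir=workdir) as tmp:
            inp = Path(tmp) / "input.smi"
            outp = Path(tmp) / "scores.csv"
            chem.write_smi(inp, [(f"m{i}", m.smiles_canonical) for i, m in enumerate(mols)])
            cmd = command_template.format(input=str(inp), output=str(outp))
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise AdapterError(
                    f"external scorer exited {proc.returncode}: {proc.stderr[-2000:]}"
                )
            if not outp.exists():
                raise AdapterError(f"external scorer wrote no output file {outp}")
            table: dict[str, float] = {}
            with open(outp) as fh:
                for row in csv.reader(fh):
                    if not row or row[0].strip().lower() == "id":
                        continue
                    if len(row) < 2:
                        raise AdapterError(f"malformed score row: {row!r}")
                    try:
                        table[row[0].strip()] = float(row[1])
                    except ValueError as exc:
                        raise AdapterError(f"non-numeric score in row {row!r}") from exc
            return [table.get(f"m{i}", FAILURE_SCORE) for i in range(len(mols))]

    return scorer
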