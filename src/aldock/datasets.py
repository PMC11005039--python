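"""Ligand score tables, Morgan fingerprints, and packed fingerprint storage.

A virtual-screening campaign starts from a *score table* — delimited text
with one row per ligand carrying an external identifier, optionally a
SMILES string, and a docking score — plus a binary fingerprint matrix used
as the feature representation for surrogate models.  This module reads and
validates those inputs into a :class:`LigandLibrary`, computes Morgan
(circular) fingerprints with RDKit, and stores fingerprint matrices in a
compact packed container (8 bits per byte, self-describing header,
content checksum).

The internal score convention is **lower = better**: empirical docking
scoring functions report more negative values for predicted tighter
binders.  Tables whose scores run the other way are negated on load and
the transform is recorded on the library, so downstream ranking code never
has to branch on direction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ScoreParseError",
    "FingerprintStoreError",
    "FingerprintSpec",
    "LigandLibrary",
    "load_score_table",
    "load_smiles_file",
    "featurize",
    "store_fingerprints",
    "load_fingerprints",
    "export_fingerprints_text",
    "library_manifest",
]

_MAGIC = "aldock-fp-v1"


class SchemaError(ValueError):
    """A required column is missing or identifiers are malformed."""


class ScoreParseError(ValueError):
    """A score field failed to parse as a finite real number."""


class FingerprintStoreError(ValueError):
    """Packed fingerprint container is corrupt or inconsistent."""


@dataclass(frozen=True)
class FingerprintSpec:
    """Morgan fingerprint parameters.

    radius 2 / 2048 bits is the convention for million-ligand runs;
    1024 bits is used in ultra-large (out-of-memory) mode to halve the
    feature matrix.
    """

    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.n_bits < 8 or self.n_bits % 8 != 0:
            raise ValueError(
                f"n_bits must be >= 8 and a multiple of 8 (packed storage), got {self.n_bits}"
            )


@dataclass
class LigandLibrary:
    """In-memory ligand collection with dense integer ids 0..N-1.

    All optional per-ligand arrays, when present, have length N.  Scores
    follow the internal lower-is-better convention; ``score_negated``
    records whether the source declared the opposite direction.
    """

    ids: np.ndarray
    external_ids: list[str] | None = None
    smiles: list[str] | None = None
    fingerprints: np.ndarray | None = None
    scores: np.ndarray | None = None
    score_negated: bool = False

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_bits(self) -> int | None:
        return None if self.fingerprints is None else self.fingerprints.shape[1]

    def validate(self) -> None:
        n = len(self.ids)
        if n < 1:
            raise ValueError("library must contain at least one ligand")
        if not np.array_equal(self.ids, np.arange(n)):
            raise ValueError("ids must be dense integers 0..N-1")
        for name, arr in (("external_ids", self.external_ids), ("smiles", self.smiles)):
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if self.scores is not None:
            if len(self.scores) != n:
                raise ValueError(f"scores has length {len(self.scores)}, expected {n}")
            if not np.all(np.isfinite(self.scores)):
                raise ValueError("scores must all be finite")
        if self.fingerprints is not None:
            fp = self.fingerprints
            if fp.ndim != 2 or fp.shape[0] != n:
                raise ValueError(f"fingerprints shape {fp.shape} incompatible with N={n}")
            if not np.isin(fp, (0, 1)).all():
                raise ValueError("fingerprint entries must be exactly 0 or 1")
        if self.external_ids is not None and len(set(self.external_ids)) != n:
            raise SchemaError("duplicate external ids in library")


def load_score_table(
    path: str | Path,
    *,
    id_col: str = "id",
    score_col: str = "score",
    smiles_col: str | None = None,
    direction: str = "lower_better",
    sep: str | None = None,
) -> LigandLibrary:
    """Read a delimited score table into a :class:`LigandLibrary` (no fingerprints).

    Parameters
    ----------
    path:
        CSV/TSV file with a header row.  The delimiter is inferred from the
        extension (``.tsv``/``.tab`` -> tab, else comma) unless ``sep`` is given.
    direction:
        ``"lower_better"`` keeps scores as-is; ``"higher_better"`` negates
        them so the internal convention (lower = better) holds, and the
        negation is recorded on the returned library.

    Raises
    ------
    SchemaError
        missing mapped column, or duplicate external identifier.
    ScoreParseError
        a score that is not a finite real; the message names the file line.
    """
    path = Path(path)
    if direction not in ("lower_better", "higher_better"):
        raise ValueError(f"unknown score direction {direction!r}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in filter(None, (id_col, score_col, smiles_col)):
        if col not in df.columns:
            raise SchemaError(
                f"{path.name}: column {col!r} not found (have {list(df.columns)})"
            )
    raw = df[score_col]
    scores = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.flatnonzero(~np.isfinite(scores))
    if bad.size:
        i = int(bad[0])
        # +2: one for the header row, one for 1-based line numbering
        raise ScoreParseError(
            f"{path.name}: line {i + 2}: score {raw.iloc[i]!r} is not a finite number"
        )
    ext = df[id_col].tolist()
    dup = df[id_col].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(f"{path.name}: duplicate external id {ext[i]!r} at line {i + 2}")
    if direction == "higher_better":
        scores = -scores
    return LigandLibrary(
        ids=np.arange(len(df)),
        external_ids=ext,
        smiles=df[smiles_col].tolist() if smiles_col else None,
        scores=scores,
        score_negated=direction == "higher_better",
    )


def load_smiles_file(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a ``.smi`` file ("SMILES<whitespace>id" per line) -> (smiles, ids)."""
    smiles: list[str] = []
    ids: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smiles.append(parts[0])
        ids.append(parts[1].strip() if len(parts) > 1 else str(lineno - 1))
    return smiles, ids


def featurize(smiles: Sequence[str], spec: FingerprintSpec | None = None) -> np.ndarray:
    """Morgan fingerprints for a batch of SMILES -> binary uint8 matrix.

    Invalid SMILES are a hard error listing every offending index: silently
    dropping rows would desynchronize ids, scores and features.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    spec = spec or FingerprintSpec()
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=spec.radius, fpSize=spec.n_bits)
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    bad = [i for i, m in enumerate(mols) if m is None]
    if bad:
        raise ValueError(
            f"unparseable SMILES at indices {bad}: "
            f"{[smiles[i] for i in bad[:5]]}{'...' if len(bad) > 5 else ''}"
        )
    out = np.zeros((len(mols), spec.n_bits), dtype=np.uint8)
    for i, mol in enumerate(mols):
        out[i] = gen.GetFingerprintAsNumPy(mol)
    return out


def _checksum(payload: bytes) -> str:
    return hashlib.sha256(payload).hexdigest()


def store_fingerprints(matrix: np.ndarray, path: str | Path, *, radius: int = 2) -> None:
    """Write a binary fingerprint matrix packed 8 bits/byte.

    Container layout: one JSON header line (magic, N, n_bits, radius,
    sha256 of the packed payload) followed by the raw packed bytes.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise FingerprintStoreError(f"refusing to store matrix of shape {matrix.shape}")
    if matrix.shape[1] % 8 != 0:
        raise FingerprintStoreError("n_bits must be a multiple of 8 for packed storage")
    if not np.isin(matrix, (0, 1)).all():
        raise FingerprintStoreError("matrix entries must be exactly 0 or 1")
    packed = np.packbits(matrix.astype(np.uint8), axis=1)
    payload = packed.tobytes()
    header = {
        "magic": _MAGIC,
        "n": int(matrix.shape[0]),
        "n_bits": int(matrix.shape[1]),
        "radius": int(radius),
        "sha256": _checksum(payload),
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode() + b"\n")
        fh.write(payload)


def load_fingerprints(path: str | Path) -> tuple[np.ndarray, FingerprintSpec]:
    """Load a packed fingerprint container -> (binary matrix, FingerprintSpec).

    Verifies the content checksum and that the declared shape matches the
    payload size; a mismatch raises :class:`FingerprintStoreError`.
    """
    with open(path, "rb") as fh:
        header_line = fh.readline()
        payload = fh.read()
    try:
        header = json.loads(header_line)
    except json.JSONDecodeError as exc:
        raise FingerprintStoreError(f"{path}: unreadable header") from exc
    if header.get("magic") != _MAGIC:
        raise FingerprintStoreError(f"{path}: not an aldock fingerprint container")
    n, n_bits = int(header["n"]), int(header["n_bits"])
    if len(payload) != n * (n_bits // 8):
        raise FingerprintStoreError(
            f"{path}: payload of {len(payload)} bytes does not match declared "
            f"shape ({n} x {n_bits} bits)"
        )
    if _checksum(payload) != header["sha256"]:
        raise FingerprintStoreError(f"{path}: checksum mismatch, file is corrupt")
    packed = np.frombuffer(payload, dtype=np.uint8).reshape(n, n_bits // 8)
    matrix = np.unpackbits(packed, axis=1)[:, :n_bits]
    return matrix, FingerprintSpec(radius=int(header.get("radius", 2)), n_bits=n_bits)


def export_fingerprints_text(matrix: np.ndarray, path: str | Path) -> None:
    # debugging aid: one '0'/'1' string per ligand
    with open(path, "w") as fh:
        for row in np.asarray(matrix, dtype=np.uint8):
            fh.write("".join(map(str, row)) + "\n")


def library_manifest(library: LigandLibrary) -> dict:
    """JSON-serializable summary of a library (N, B, direction, checksums)."""
    manifest: dict = {
        "n_ligands": library.n,
        "n_bits": library.n_bits,
        "score_direction": "negated_on_load" if library.score_negated else "lower_better",
    }
    if library.scores is not None:
        manifest["score_sha256"] = _checksum(library.scores.tobytes())
    if library.fingerprints is not None:
        manifest["fingerprint_sha256"] = _checksum(
            np.ascontiguousarray(library.fingerprints, dtype=np.uint8).tobytes()
        )
    return manifest
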