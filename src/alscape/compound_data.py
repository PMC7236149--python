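"""Compound data model, Tanimoto similarity, and reference-landscape selection.

An activity class is a set of compounds annotated with a binary structural
fingerprint (default 1024 bits, e.g. a folded circular fingerprint) and a
potency expressed as pKi (negative decadic log of the inhibition constant).
Pairwise Tanimoto similarity over fingerprints, together with the potency
distribution, drives everything downstream: singleton filtering, 2D
projection, and the smooth/rugged reference-landscape variants used as
topology class labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VARIANT_LABELS",
    "Fingerprint",
    "Compound",
    "ActivityClass",
    "PotencySummary",
    "tanimoto",
    "tanimoto_distance",
    "pairwise_tanimoto",
    "pairwise_distance_matrix",
    "similarity_filter",
    "smooth_reference",
    "rugged_reference",
    "potency_summary",
    "read_compound_table",
    "write_compound_table",
    "ecfp_fingerprinter",
]

#: Canonical topology labels in canonical (tie-break) order.
VARIANT_LABELS = ("heterogeneous", "rugged", "smooth")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint.

    Bits are stored most-significant-first with respect to the hex
    serialization: ``Fingerprint.from_hex("80")`` sets bit 0 only.
    """

    bits: np.ndarray  # bool vector

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=bool)
        object.__setattr__(self, "bits", b)
        if b.ndim != 1 or b.size == 0:
            raise ValueError("fingerprint must be a non-empty 1D bit vector")

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_bitstring(cls, s: str) -> "Fingerprint":
        if not s or set(s) - {"0", "1"}:
            raise ValueError(f"invalid bitstring {s!r}")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) == ord("1"))

    @classmethod
    def from_hex(cls, s: str, n_bits: int | None = None) -> "Fingerprint":
        s = s.strip().lower().removeprefix("0x")
        if len(s) % 2:
            s = "0" + s
        try:
            raw = bytes.fromhex(s)
        except ValueError as exc:
            raise ValueError(f"invalid hex fingerprint {s!r}") from exc
        bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8)).astype(bool)
        if n_bits is not None:
            if n_bits > bits.size:
                raise ValueError("hex string shorter than requested bit length")
            bits = bits[:n_bits]
        return cls(bits)

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def to_hex(self) -> str:
        n = self.bits.size
        padded = np.zeros(-(-n // 8) * 8, dtype=bool)
        padded[:n] = self.bits
        return np.packbits(padded).tobytes().hex()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.bits.size == other.bits.size and bool(
            np.array_equal(self.bits, other.bits)
        )

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())


@dataclass(frozen=True)
class Compound:
    id: str
    fingerprint: Fingerprint
    potency: float  # pKi

    def __post_init__(self) -> None:
        if not np.isfinite(self.potency):
            raise ValueError(f"compound {self.id!r}: potency must be finite")


@dataclass
class ActivityClass:
    """Named, ordered collection of compounds plus a topology variant label."""

    name: str
    compounds: list[Compound]
    variant: str = "heterogeneous"
    _fp_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_LABELS:
            raise ValueError(f"unknown variant {self.variant!r}")
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise ValueError(f"class {self.name!r}: compound ids not unique")
        lengths = {len(c.fingerprint) for c in self.compounds}
        if len(lengths) > 1:
            raise ValueError(f"class {self.name!r}: mixed fingerprint lengths {lengths}")

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    @property
    def potencies(self) -> np.ndarray:
        return np.array([c.potency for c in self.compounds], dtype=float)

    @property
    def fingerprint_matrix(self) -> np.ndarray:
        """(n, n_bits) boolean matrix, row order = compound order."""
        if self._fp_cache is None or self._fp_cache.shape[0] != len(self.compounds):
            self._fp_cache = np.array([c.fingerprint.bits for c in self.compounds])
        return self._fp_cache

    def subset(self, indices: np.ndarray | list[int], variant: str | None = None) -> "ActivityClass":
        return ActivityClass(
            name=self.name,
            compounds=[self.compounds[i] for i in indices],
            variant=self.variant if variant is None else variant,
        )


@dataclass(frozen=True)
class PotencySummary:
    min: float
    max: float
    q1: float
    q3: float
    iqr: float
    septile_boundaries: tuple[float, ...]


# ---------------------------------------------------------------------------
# Tanimoto similarity
# ---------------------------------------------------------------------------

def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient Tc(A, B) = |A∩B| / (|A| + |B| − |A∩B|)."""
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = a.popcount + b.popcount - inter
    if union == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return inter / union


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto distance 1 − Tc(A, B)."""
    return 1.0 - tanimoto(a, b)


def _pairwise_tc(fp_a: np.ndarray, fp_b: np.ndarray) -> np.ndarray:
    """Tc between all rows of two boolean matrices."""
    a = fp_a.astype(np.int32)
    b = fp_b.astype(np.int32)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    if np.any(union == 0):
        raise ValueError("Tanimoto undefined: all-zero fingerprint pair present")
    return inter / union


def pairwise_tanimoto(cls: ActivityClass) -> np.ndarray:
    """Symmetric n×n Tanimoto similarity matrix, unit diagonal."""
    return _pairwise_tc(cls.fingerprint_matrix, cls.fingerprint_matrix)


def pairwise_distance_matrix(cls: ActivityClass) -> np.ndarray:
    """Symmetric n×n Tanimoto distance matrix (1 − Tc), zero diagonal."""
    d = 1.0 - pairwise_tanimoto(cls)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Filtering and reference-landscape selection
# ---------------------------------------------------------------------------

def similarity_filter(cls: ActivityClass, threshold: float = 0.4) -> ActivityClass:
    """Drop singletons: keep compounds with Tc ≥ ``threshold`` to ≥ 1 other.

    Tanimoto neighborship is mutual, so removing a singleton can never create
    new singletons; a single pass is exact.
    """
    n = len(cls)
    if n == 0:
        return cls.subset([])
    if n == 1:
        warnings.warn(f"class {cls.name!r}: single compound has no neighbors; empty result")
        return cls.subset([])
    tc = pairwise_tanimoto(cls)
    np.fill_diagonal(tc, -np.inf)
    keep = np.flatnonzero(tc.max(axis=1) >= threshold)
    if keep.size == 0:
        warnings.warn(f"class {cls.name!r}: similarity filter removed all compounds")
    return cls.subset(keep)


def potency_summary(cls: ActivityClass) -> PotencySummary:
    """Quartile/septile summary of the potency distribution.

    Quantiles use linear interpolation between order statistics.
    """
    p = cls.potencies
    if p.size == 0:
        raise ValueError("empty class has no potency summary")
    q1, q3 = np.quantile(p, [0.25, 0.75])
    sept = tuple(np.quantile(p, np.arange(1, 7) / 7.0))
    return PotencySummary(
        min=float(p.min()), max=float(p.max()),
        q1=float(q1), q3=float(q3), iqr=float(q3 - q1),
        septile_boundaries=sept,
    )


def smooth_reference(cls: ActivityClass) -> ActivityClass:
    """Smooth reference landscape: compounds in the interquartile potency range.

    Keeps compounds with q1 ≤ pKi ≤ q3 (closed interval), exaggerating SAR
    continuity by discarding potency extremes.
    """
    if len(cls) < 4:
        raise ValueError(f"class {cls.name!r}: need ≥ 4 compounds for quartile selection")
    s = potency_summary(cls)
    p = cls.potencies
    keep = np.flatnonzero((p >= s.q1) & (p <= s.q3))
    if keep.size < 2:
        raise ValueError(f"class {cls.name!r}: interquartile selection left < 2 compounds")
    return cls.subset(keep, variant="smooth")


def rugged_reference(cls: ActivityClass) -> ActivityClass:
    """Rugged reference landscape: compounds in the 1st, 3rd, 5th and 7th septile.

    Compounds are sorted by potency (ties broken by id) and partitioned into
    seven consecutive bins of near-equal count (remainder to the earliest
    bins); the odd bins are kept. Alternating potency bands exaggerate SAR
    discontinuity while retaining the full potency range.
    """
    n = len(cls)
    if n < 7:
        raise ValueError(f"class {cls.name!r}: need ≥ 7 compounds for septile selection")
    order = sorted(range(n), key=lambda i: (cls.compounds[i].potency, cls.compounds[i].id))
    base, rem = divmod(n, 7)
    sizes = [base + (1 if b < rem else 0) for b in range(7)]
    keep: list[int] = []
    start = 0
    for b, size in enumerate(sizes):
        if b % 2 == 0:  # septiles 1, 3, 5, 7
            keep.extend(order[start:start + size])
        start += size
    return cls.subset(sorted(keep), variant="rugged")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _decode_fingerprint(value: str, fmt: str, n_bits: int | None) -> Fingerprint:
    value = str(value).strip()
    if fmt == "auto":
        fmt = "bitstring" if set(value) <= {"0", "1"} else "hex"
    if fmt == "bitstring":
        return Fingerprint.from_bitstring(value)
    if fmt == "hex":
        return Fingerprint.from_hex(value, n_bits=n_bits)
    raise ValueError(f"unknown fingerprint format {fmt!r}")


def read_compound_table(
    path,
    name: str | None = None,
    id_col: str = "id",
    potency_col: str = "potency",
    fingerprint_col: str = "fingerprint",
    smiles_col: str = "smiles",
    fingerprint_format: str = "auto",
    n_bits: int | None = None,
    fingerprinter=None,
) -> ActivityClass:
    """Read an activity class from CSV.

    Expected header: ``id, potency, fingerprint`` with the fingerprint as a
    '0'/'1' bitstring or hex (most-significant-bit-first). Alternatively a
    ``smiles`` column combined with a ``fingerprinter`` callable
    (smiles → Fingerprint), e.g. :func:`ecfp_fingerprinter`. Malformed rows
    are reported with their line numbers in a single error.
    """
    df = pd.read_csv(path, dtype=str)
    use_smiles = fingerprinter is not None and smiles_col in df.columns
    required = [id_col, potency_col] + ([] if use_smiles else [fingerprint_col])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")

    compounds: list[Compound] = []
    errors: list[str] = []
    fp_len: int | None = None
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            potency = float(row[potency_col])
            if not np.isfinite(potency):
                raise ValueError(f"non-finite potency {row[potency_col]!r}")
            if use_smiles:
                fp = fingerprinter(str(row[smiles_col]))
            else:
                fp = _decode_fingerprint(row[fingerprint_col], fingerprint_format, n_bits)
            if fp.popcount == 0:
                raise ValueError("all-zero fingerprint")
            if fp_len is None:
                fp_len = len(fp)
            elif len(fp) != fp_len:
                raise ValueError(f"fingerprint length {len(fp)} != {fp_len}")
            compounds.append(Compound(str(row[id_col]), fp, potency))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    cls_name = name if name is not None else str(path)
    return ActivityClass(name=cls_name, compounds=compounds)


def write_compound_table(cls: ActivityClass, path, fingerprint_format: str = "bitstring") -> None:
    """Write an activity class in the CSV dialect of :func:`read_compound_table`."""
    rows = []
    for c in cls.compounds:
        fp = c.fingerprint.to_bitstring() if fingerprint_format == "bitstring" else c.fingerprint.to_hex()
        rows.append({"id": c.id, "potency": c.potency, "fingerprint": fp})
    pd.DataFrame(rows).to_csv(path, index=False)


def ecfp_fingerprinter(n_bits: int = 1024, radius: int = 2):
    """Pluggable SMILES fingerprinter: hashed circular substructures.

    Returns a callable ``smiles -> Fingerprint`` (Morgan/ECFP-style, radius 2
    i.e. bond diameter 4, folded to ``n_bits``). Requires rdkit.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)

    def fingerprint(smiles: str) -> Fingerprint:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES {smiles!r}")
        bv = gen.GetFingerprint(mol)
        bits = np.zeros(n_bits, dtype=bool)
        bits[list(bv.GetOnBits())] = True
        return Fingerprint(bits)

    return fingerprint
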