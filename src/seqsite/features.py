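"""Per-residue feature embedding for binding-residue prediction.

Each residue of a protein is embedded in a d=30 feature space built from
seven feature groups, in this fixed column order:

====== ======= =====================================================
cols   width   feature
====== ======= =====================================================
0-19   20      PSSM log-odds squashed by y = 1 / (1 + 2**(-x))
20     1       relative solvent accessibility (RSA), raw fraction
21-23  3       secondary-structure propensities (helix, strand, coil)
24-25  2       phi / psi dihedral angles, divided by 360
26-27  2       conservation scores (relative entropy, Jensen-Shannon)
28     1       residue type, index / 21 (dummy residue = index 20)
29     1       position embedding, i / L with i 1-based
====== ======= =====================================================

RSA, SS and CS values are consumed as given; no buried/exposed
discretisation is applied.  The 20 standard amino acids are indexed in
alphabetical one-letter order; the dummy (padding) residue takes index 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "DUMMY_RESIDUE",
    "RESIDUE_INDEX",
    "N_FEATURES",
    "FEATURE_COLUMNS",
    "ProteinRecord",
    "FeatureMap",
    "normalize_pssm",
    "normalize_dihedral",
    "encode_residue_type",
    "position_embeddings",
    "conservation_scores",
    "assemble_feature_map",
    "dummy_feature_row",
]

#: The 20 standard amino acids in alphabetical one-letter order (indices 0-19).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Padding token used to equalise sequence lengths within a batch (index 20).
DUMMY_RESIDUE = "X"
RESIDUE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
RESIDUE_INDEX[DUMMY_RESIDUE] = 20
N_RESIDUE_TYPES = 21

N_FEATURES = 30
FEATURE_COLUMNS = (
    [f"pssm_{i}" for i in range(1, 21)]
    + ["rsa", "ss_h", "ss_e", "ss_c", "phi", "psi", "cs_re", "cs_jsd", "rt", "pe"]
)


@dataclass
class ProteinRecord:
    """A protein with optional per-residue labels and raw feature table."""

    id: str
    sequence: str
    labels: np.ndarray | None = None  # (L,) int {0,1}
    features: "np.ndarray | None" = None  # (L, 28) raw columns, no rt/pe
    feature_table: "object | None" = field(default=None, repr=False)  # pandas frame

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureMap:
    """The m x 30 network input for one protein."""

    values: np.ndarray
    protein_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"FeatureMap must be m x {N_FEATURES}, got {self.values.shape}"
            )

    @property
    def length(self) -> int:
        return self.values.shape[0]


def _require_finite(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{what} contains non-finite values")
    return x


def normalize_pssm(scores) -> np.ndarray:
    """Squash raw PSSM log-odds into (0, 1) with y = 1 / (1 + 2**(-x)).

    The base-2 logistic matches the log2-odds scale of profile scores;
    it is strictly increasing and maps 0 to exactly 0.5.
    """
    x = _require_finite(scores, "PSSM scores")
    return 1.0 / (1.0 + np.exp2(-x))


def normalize_dihedral(angle) -> np.ndarray:
    """Scale dihedral angles (degrees) by 1/360.

    Negative angles pass through unchanged (a -90 degree phi becomes -0.25);
    callers that want the [0, 360) convention can wrap beforehand via
    ``angle % 360``.
    """
    x = _require_finite(angle, "dihedral angles")
    return x / 360.0


def encode_residue_type(token: str, lenient: bool = False) -> float:
    """Map a one-letter residue token to index/21 in [0, 1).

    The dummy residue encodes as 20/21.  Unknown tokens are rejected unless
    ``lenient`` is set, in which case they are treated as the dummy residue.
    """
    token = token.upper()
    if token not in RESIDUE_INDEX:
        if lenient:
            token = DUMMY_RESIDUE
        else:
            raise ValueError(f"unknown residue token {token!r}")
    return RESIDUE_INDEX[token] / N_RESIDUE_TYPES


def position_embeddings(length: int) -> np.ndarray:
    """Absolute-position feature PE_i = i / L, i = 1..L, all in (0, 1]."""
    if length < 1:
        raise ValueError(f"sequence length must be >= 1, got {length}")
    return np.arange(1, length + 1, dtype=np.float64) / length


def conservation_scores(p, q, tol: float = 1e-6) -> tuple[float, float]:
    """Relative entropy and Jensen-Shannon divergence of a profile column.

    Both arguments must be probability vectors over the 20 amino acids.
    Logarithms are base 2, so JSD is bounded by 1.  This is a convenience
    for synthesising conservation features; precomputed scores from an
    alignment pipeline are accepted verbatim by :func:`assemble_feature_map`.
    """
    p = _require_finite(p, "column distribution")
    q = _require_finite(q, "background distribution")
    for name, v in (("column", p), ("background", q)):
        if v.min() < 0 or abs(v.sum() - 1.0) > tol:
            raise ValueError(f"{name} distribution is not normalized")

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        nz = a > 0
        return float(np.sum(a[nz] * np.log2(a[nz] / b[nz])))

    re = kl(p, q)
    mid = 0.5 * (p + q)
    jsd = 0.5 * kl(p, mid) + 0.5 * kl(q, mid)
    return re, jsd


def dummy_feature_row(pe: float = 0.0) -> np.ndarray:
    """Embedded row for a padding residue: all-zero raw features, dummy RT.

    PE is 0 by convention for padding rows (real residues have PE in (0,1]).
    """
    row = np.zeros(N_FEATURES)
    row[:20] = 0.5  # sigma2(0)
    row[28] = 20 / N_RESIDUE_TYPES
    row[29] = pe
    return row


def assemble_feature_map(
    sequence: str,
    pssm: np.ndarray,
    rsa: np.ndarray,
    ss: np.ndarray,
    phi: np.ndarray,
    psi: np.ndarray,
    cs_re: np.ndarray,
    cs_jsd: np.ndarray,
    protein_id: str = "",
    lenient_tokens: bool = False,
) -> FeatureMap:
    """Assemble the m x 30 feature map from raw per-residue features.

    PSSM columns are squashed, dihedrals divided by 360, residue type and
    position embeddings computed from the sequence; RSA, SS and CS pass
    through unchanged.  All groups must cover the same m residues.
    """
    m = len(sequence)
    if m == 0:
        raise ValueError("empty sequence")
    pssm = _require_finite(pssm, "PSSM").reshape(m, -1) if np.asarray(pssm).size else None
    if pssm is None or pssm.shape != (m, 20):
        raise ValueError(f"PSSM must be {m} x 20")
    groups = {
        "rsa": np.asarray(rsa, dtype=np.float64).reshape(-1),
        "phi": np.asarray(phi, dtype=np.float64).reshape(-1),
        "psi": np.asarray(psi, dtype=np.float64).reshape(-1),
        "cs_re": np.asarray(cs_re, dtype=np.float64).reshape(-1),
        "cs_jsd": np.asarray(cs_jsd, dtype=np.float64).reshape(-1),
    }
    for name, g in groups.items():
        if g.shape[0] != m:
            raise ValueError(f"feature group {name!r} has length {g.shape[0]}, expected {m}")
    ss = np.asarray(ss, dtype=np.float64)
    if ss.shape != (m, 3):
        raise ValueError(f"SS must be {m} x 3")
    if ss.min() < 0 or ss.max() > 1:
        raise ValueError("SS propensities must lie in [0, 1]")

    out = np.empty((m, N_FEATURES))
    out[:, :20] = normalize_pssm(pssm)
    out[:, 20] = groups["rsa"]
    out[:, 21:24] = ss
    out[:, 24] = normalize_dihedral(groups["phi"])
    out[:, 25] = normalize_dihedral(groups["psi"])
    out[:, 26] = groups["cs_re"]
    out[:, 27] = groups["cs_jsd"]
    out[:, 28] = [encode_residue_type(t, lenient=lenient_tokens) for t in sequence]
    out[:, 29] = position_embeddings(m)
    return FeatureMap(out, protein_id=protein_id)


def feature_map_from_record(record: ProteinRecord, lenient_tokens: bool = False) -> FeatureMap:
    """Assemble a feature map from a :class:`ProteinRecord` carrying raw features."""
    if record.features is None:
        raise ValueError(f"protein {record.id!r} has no raw features")
    f = np.asarray(record.features, dtype=np.float64)
    if f.shape != (len(record), 28):
        raise ValueError(
            f"raw feature block for {record.id!r} must be {len(record)} x 28, got {f.shape}"
        )
    return assemble_feature_map(
        record.sequence,
        pssm=f[:, :20],
        rsa=f[:, 20],
        ss=f[:, 21:24],
        phi=f[:, 24],
        psi=f[:, 25],
        cs_re=f[:, 26],
        cs_jsd=f[:, 27],
        protein_id=record.id,
        lenient_tokens=lenient_tokens,
    )
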