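"""Site similarity kernels and their combination.

Two complementary views of a candidate site are turned into kernels over
sites:

* the *local sequence kernel* ``K_seq`` — the positionwise BLOSUM62
  similarity of two 21-residue windows, min-max normalized to [0, 1];
* the *Gaussian interaction-profile (GIP) kernel* ``K_GIP`` — an RBF
  kernel ``exp(-gamma * ||A_i - A_j||^2)`` on the binary rows of the
  site x PTM adjacency matrix of a bipartite site-modification network.

The two are combined as a non-negative weighted sum ``K = sum_d beta_d
K_d`` and passed to an SVM as a precomputed Gram matrix.  During
cross-validation the adjacency column of the PTM being predicted must be
zeroed for held-out sites (``mask_profiles``) and the GIP kernel
recomputed, otherwise the kernel would leak the very labels under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .windows import PeptideWindow, SubstitutionMatrix

SYMMETRY_TOL = 1e-12
PSD_TOL = 1e-10

KERNEL_KINDS = ("raw_similarity", "seq_kernel", "gip_kernel", "combined")


@dataclass
class KernelMatrix:
    """A symmetric site-by-site similarity matrix with its id ordering."""

    site_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        m = len(self.site_ids)
        if self.values.shape != (m, m):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match {m} site ids"
            )
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if m and np.abs(self.values - self.values.T).max() > SYMMETRY_TOL:
            raise ValueError("kernel matrix is not symmetric")

    @property
    def m(self) -> int:
        return len(self.site_ids)

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: header of site ids, one id-prefixed row per site."""
        with open(path, "w") as fh:
            fh.write("site_id\t" + "\t".join(self.site_ids) + "\n")
            for sid, row in zip(self.site_ids, self.values):
                fh.write(sid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "KernelMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in parts[1:]])
        return cls(header, np.array(rows, dtype=float), kind)


@dataclass
class InteractionProfileMatrix:
    """Binary site x PTM adjacency of the site-modification network.

    Row *i* is the interaction profile of site *i*: entry (i, p) is 1
    iff site *i* is experimentally known to carry PTM *p*.
    """

    site_ids: list[str]
    ptm_names: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.site_ids), len(self.ptm_names)):
            raise ValueError(
                f"adjacency shape {self.A.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.ptm_names)} PTMs"
            )
        if self.A.size and not np.isin(self.A, (0, 1)).all():
            raise ValueError("adjacency matrix must be binary")
        self.A = self.A.astype(np.int8)

    def profile(self, site_id: str) -> np.ndarray:
        return self.A[self.site_ids.index(site_id)]

    def to_dense_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site_id\t" + "\t".join(self.ptm_names) + "\n")
            for sid, row in zip(self.site_ids, self.A):
                fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def from_dense_tsv(cls, path: str | Path) -> "InteractionProfileMatrix":
        with open(path) as fh:
            ptm_names = fh.readline().rstrip("\n").split("\t")[1:]
            site_ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                site_ids.append(parts[0])
                rows.append([int(v) for v in parts[1:]])
        return cls(site_ids, ptm_names, np.array(rows, dtype=np.int8))

    def to_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site_id\tptm_name\n")
            for i, sid in enumerate(self.site_ids):
                for j, name in enumerate(self.ptm_names):
                    if self.A[i, j]:
                        fh.write(f"{sid}\t{name}\n")

    @classmethod
    def from_edge_list(
        cls,
        path: str | Path,
        site_ids: Sequence[str],
        ptm_names: Sequence[str],
    ) -> "InteractionProfileMatrix":
        sidx = {s: i for i, s in enumerate(site_ids)}
        pidx = {p: j for j, p in enumerate(ptm_names)}
        A = np.zeros((len(site_ids), len(ptm_names)), dtype=np.int8)
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != "site_id\tptm_name":
                raise ValueError(f"{path}: expected 'site_id<TAB>ptm_name' header")
            for line in fh:
                sid, name = line.rstrip("\n").split("\t")
                if sid not in sidx:
                    raise ValueError(f"{path}: unknown site id {sid!r}")
                if name not in pidx:
                    raise ValueError(f"{path}: unknown PTM name {name!r}")
                A[sidx[sid], pidx[name]] = 1
        return cls(list(site_ids), list(ptm_names), A)


@dataclass
class KernelConfig:
    """Kernel hyperparameters.

    gamma : GIP bandwidth; small values flatten the kernel, large values
        localize it.  Default 0.001.
    betas : non-negative weight per component kernel (sequence, GIP).
    psd_repair : clip negative eigenvalues of the combined kernel.  The
        GIP kernel is positive semi-definite by construction but the
        min-max-normalized BLOSUM62 sum is not guaranteed to be, so this
        guard is available; off by default.
    """

    gamma: float = 0.001
    betas: tuple[float, ...] = (0.5, 0.5)
    psd_repair: bool = False

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        self.betas = tuple(float(b) for b in self.betas)
        if any(b < 0 for b in self.betas):
            raise ValueError(f"betas must be non-negative, got {self.betas}")
        if not any(b > 0 for b in self.betas):
            raise ValueError("at least one beta must be positive")


def _encode_windows(
    windows: Sequence[PeptideWindow], matrix: SubstitutionMatrix
) -> np.ndarray:
    lengths = {len(w) for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"windows have mixed lengths {sorted(lengths)}")
    return np.stack([matrix.encode(w.residues) for w in windows])


def seq_similarity_matrix(
    windows: Sequence[PeptideWindow], matrix: SubstitutionMatrix
) -> KernelMatrix:
    """Raw positionwise BLOSUM62 similarity between all window pairs.

    Entry (i, j) is the sum over the 21 aligned positions of the
    substitution score of the two residues.  Integer-valued, symmetric.
    """
    enc = _encode_windows(windows, matrix)
    S = _positionwise_sum(enc, enc, matrix.score_table)
    return KernelMatrix([w.site_id for w in windows], S, "raw_similarity")


def seq_similarity_cross(
    rows: Sequence[PeptideWindow],
    cols: Sequence[PeptideWindow],
    matrix: SubstitutionMatrix,
) -> np.ndarray:
    """Raw similarity block between two window collections (rows x cols)."""
    enc_r = _encode_windows(rows, matrix)
    enc_c = _encode_windows(cols, matrix)
    if enc_r.shape[1] != enc_c.shape[1]:
        raise ValueError("windows have mixed lengths")
    return _positionwise_sum(enc_r, enc_c, matrix.score_table)


def _positionwise_sum(
    enc_r: np.ndarray, enc_c: np.ndarray, table: np.ndarray
) -> np.ndarray:
    S = np.zeros((enc_r.shape[0], enc_c.shape[0]), dtype=np.int64)
    for x in range(enc_r.shape[1]):
        S += table[np.ix_(enc_r[:, x], enc_c[:, x])]
    return S


def minmax_normalize(S: KernelMatrix) -> tuple[KernelMatrix, float, float]:
    """Affinely map a raw similarity matrix onto [0, 1].

    Returns the normalized kernel and the (min, max) constants so that
    out-of-sample blocks can be mapped through the same transform.
    """
    if S.kind != "raw_similarity":
        raise ValueError(f"expected a raw_similarity matrix, got {S.kind!r}")
    mn, mx = float(S.values.min()), float(S.values.max())
    if mx == mn:
        raise ValueError("similarity matrix is constant; normalization undefined")
    K = (S.values - mn) / (mx - mn)
    return KernelMatrix(list(S.site_ids), K, "seq_kernel"), mn, mx


def apply_normalization(
    S_cross: np.ndarray, min_val: float, max_val: float
) -> np.ndarray:
    """Apply stored min-max constants to a cross block, clamping to [0, 1]."""
    if max_val <= min_val:
        raise ValueError("max_val must exceed min_val")
    K = (np.asarray(S_cross, dtype=float) - min_val) / (max_val - min_val)
    return np.clip(K, 0.0, 1.0)


def gip_kernel(profiles: InteractionProfileMatrix, gamma: float) -> KernelMatrix:
    """Gaussian interaction-profile kernel over sites.

    ``exp(-gamma * ||A_i - A_j||^2)``; for binary profiles the squared
    Euclidean distance is the Hamming distance between the rows.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    K = _gip_block(profiles.A, profiles.A, gamma)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(list(profiles.site_ids), K, "gip_kernel")


def gip_cross(A_rows: np.ndarray, A_cols: np.ndarray, gamma: float) -> np.ndarray:
    """GIP kernel block between two profile sets (rows x cols)."""
    return _gip_block(np.asarray(A_rows), np.asarray(A_cols), gamma)


def _gip_block(A_rows: np.ndarray, A_cols: np.ndarray, gamma: float) -> np.ndarray:
    D2 = cdist(A_rows.astype(float), A_cols.astype(float), "sqeuclidean")
    return np.exp(-gamma * D2)


def mask_profiles(
    profiles: InteractionProfileMatrix,
    test_site_ids: Sequence[str] | set[str],
    target_ptm: str,
) -> InteractionProfileMatrix:
    """Zero the target-PTM column for held-out sites.

    Held-out sites keep their other known annotations (cross-PTM
    relationships are legitimate inputs); only the labels being
    predicted are removed.  Training rows are untouched.
    """
    if target_ptm not in profiles.ptm_names:
        raise ValueError(f"unknown target PTM {target_ptm!r}")
    col = profiles.ptm_names.index(target_ptm)
    sidx = {s: i for i, s in enumerate(profiles.site_ids)}
    unknown = [s for s in test_site_ids if s not in sidx]
    if unknown:
        raise ValueError(f"unknown site ids {unknown[:5]!r}")
    A = profiles.A.copy()
    rows = [sidx[s] for s in test_site_ids]
    A[rows, col] = 0
    return InteractionProfileMatrix(
        list(profiles.site_ids), list(profiles.ptm_names), A
    )


def combine_kernels(
    components: Sequence[KernelMatrix], betas: Sequence[float]
) -> KernelMatrix:
    """Non-negative weighted sum of component kernels, K = sum_d beta_d K_d."""
    if len(components) != len(betas):
        raise ValueError(
            f"{len(components)} kernels but {len(betas)} weights"
        )
    if any(b < 0 for b in betas):
        raise ValueError(f"betas must be non-negative, got {tuple(betas)}")
    ids = components[0].site_ids
    for comp in components[1:]:
        if comp.site_ids != ids:
            raise ValueError("component kernels have mismatched site-id ordering")
    K = np.zeros_like(components[0].values, dtype=float)
    for beta, comp in zip(betas, components):
        K += beta * comp.values
    return KernelMatrix(list(ids), K, "combined")


def combine_blocks(
    blocks: Sequence[np.ndarray], betas: Sequence[float]
) -> np.ndarray:
    """Weighted sum of rectangular cross blocks (same shape, same ordering)."""
    if len(blocks) != len(betas):
        raise ValueError(f"{len(blocks)} blocks but {len(betas)} weights")
    out = np.zeros_like(np.asarray(blocks[0], dtype=float))
    for beta, block in zip(betas, blocks):
        out += beta * np.asarray(block, dtype=float)
    return out


def nearest_psd(K: KernelMatrix) -> KernelMatrix:
    """Project a symmetric kernel onto the PSD cone by eigenvalue clipping.

    A kernel that is already PSD is returned unchanged up to the
    reconstruction round-off (< 1e-10).
    """
    w, V = np.linalg.eigh(K.values)
    if w.min() >= 0:
        return K
    repaired = (V * np.clip(w, 0.0, None)) @ V.T
    repaired = (repaired + repaired.T) / 2.0
    return KernelMatrix(list(K.site_ids), repaired, K.kind)
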