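"""Synthetic motif-bearing datasets with correlated site-PTM networks.

Real PTM sites tend to sit inside conserved local sequence motifs, and
a residue modified by one PTM is more likely than background to carry
related modifications — the two regularities the sequence kernel and
the GIP kernel exploit.  This generator emulates both with explicit
dials:

* positives draw each consensus position of a 21-mer motif with
  probability ``match_prob`` (otherwise from background frequencies);
  negatives are pure background around the same central residue;
* positives carry each non-target "helper" annotation with probability
  ``co_occurrence_prob``, negatives with ``background_prob``; the
  target-PTM column marks the positives themselves (and is masked
  during cross-validation).

Setting ``match_prob`` to the background frequency and
``co_occurrence_prob`` equal to ``background_prob`` yields a dataset
with no signal at all, which is how chance-level calibration is tested.
Every draw flows from a single seed, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import run_cv
from .kernels import InteractionProfileMatrix, KernelConfig
from .model import LabeledDataset, ModelParams
from .windows import (
    STANDARD_AA,
    SITE_RESIDUES,
    PeptideWindow,
    ProteinRecord,
    SiteAnnotation,
)

WINDOW_LEN = 21
CENTER = WINDOW_LEN // 2
WILDCARD = "."

#: A fully specified kinase-like consensus context (flanks around the site).
_CONSENSUS_FLANKS = ("LQRRASVAGL", "PEDGSWFTKE")


def full_consensus(residue: str = "S") -> str:
    """A deterministic fully specified 21-mer consensus centred on ``residue``."""
    if residue not in SITE_RESIDUES:
        raise ValueError(f"central residue must be S/T/Y, got {residue!r}")
    return _CONSENSUS_FLANKS[0] + residue + _CONSENSUS_FLANKS[1]


@dataclass
class MotifSpec:
    """Sequence-signal model for positive windows.

    consensus : length-21 pattern; ``.`` marks wildcard positions drawn
        from background at any match_prob.
    match_prob : total probability a positive carries the consensus
        residue at a consensus position (the forcing rate is corrected
        for background coincidences, so setting match_prob to the
        background frequency of the consensus residue gives an exact
        null with no sequence signal).
    background_freqs : residue -> frequency for background draws;
        uniform over the 20 standard residues by default.
    """

    consensus: str
    match_prob: float = 0.9
    background_freqs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.consensus) != WINDOW_LEN:
            raise ValueError(
                f"consensus must have length {WINDOW_LEN}, got {len(self.consensus)}"
            )
        if self.consensus[CENTER] not in SITE_RESIDUES:
            raise ValueError("central consensus position must be S, T or Y")
        if not 0.0 <= self.match_prob <= 1.0:
            raise ValueError(f"match_prob must be in [0, 1], got {self.match_prob}")
        if self.background_freqs is None:
            self.background_freqs = {a: 1.0 / len(STANDARD_AA) for a in STANDARD_AA}
        total = sum(self.background_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")

    @property
    def central(self) -> str:
        return self.consensus[CENTER]


@dataclass
class NetworkSpec:
    """Annotation-signal model for the site-PTM bipartite network.

    n_ptms : number of PTM columns including the target.
    co_occurrence_prob : probability a positive site carries each
        non-target helper annotation.
    background_prob : the same probability for negative sites.
    target_included : whether positives get a 1 in the target column
        (masked for held-out sites during cross-validation).
    """

    n_ptms: int = 8
    co_occurrence_prob: float = 0.6
    background_prob: float = 0.05
    target_included: bool = True

    def __post_init__(self) -> None:
        if self.n_ptms < 1:
            raise ValueError("n_ptms must be >= 1")
        if not 0.0 <= self.background_prob <= self.co_occurrence_prob <= 1.0:
            raise ValueError(
                "need 0 <= background_prob <= co_occurrence_prob <= 1, got "
                f"{self.background_prob} / {self.co_occurrence_prob}"
            )


@dataclass
class SyntheticDataset:
    """All aligned views of one generated dataset."""

    proteins: list[ProteinRecord]
    windows: list[PeptideWindow]
    sites: list[SiteAnnotation]
    profiles: InteractionProfileMatrix
    data: LabeledDataset

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write FASTA + site table + dense adjacency under ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "proteins.fasta",
            "sites": out_dir / "sites.tsv",
            "adjacency": out_dir / "adjacency.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for prot in self.proteins:
                fh.write(f">{prot.id}\n{prot.sequence}\n")
        with open(paths["sites"], "w") as fh:
            fh.write("protein_id\tposition\tresidue\tannotations\ttask_label\n")
            for site in self.sites:
                label = "" if site.task_label is None else f"{site.task_label:+d}"
                fh.write(
                    f"{site.protein_id}\t{site.position}\t{site.residue}\t"
                    f"{';'.join(sorted(site.annotations))}\t{label}\n"
                )
        self.profiles.to_dense_tsv(paths["adjacency"])
        return paths


def _draw_background(rng: np.random.Generator, freqs: dict[str, float], size: int):
    letters = np.array(list(freqs.keys()))
    probs = np.array(list(freqs.values()))
    return rng.choice(letters, size=size, p=probs / probs.sum())


def generate_dataset(
    n_pos: int,
    n_neg: int,
    motif: MotifSpec,
    network: NetworkSpec,
    seed: int,
    target_ptm: str = "targetPTM",
) -> SyntheticDataset:
    """Generate aligned windows, annotations and network for one binary task.

    Each site lives on its own 21-residue synthetic protein with the
    candidate residue at position 11, so the written files round-trip
    through the standard readers without padding effects.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.array([1] * n_pos + [-1] * n_neg)

    # forcing rate q with q + (1-q)*f_c = match_prob, f_c the background
    # frequency of the consensus residue: background draws that coincide
    # with the consensus already contribute f_c of the match probability
    force_prob = np.zeros(WINDOW_LEN)
    for x, c in enumerate(motif.consensus):
        if c != WILDCARD:
            f_c = motif.background_freqs.get(c, 0.0)
            if f_c < 1.0:
                force_prob[x] = max(0.0, (motif.match_prob - f_c) / (1.0 - f_c))

    sequences = []
    for i in range(n):
        background = _draw_background(rng, motif.background_freqs, WINDOW_LEN)
        chars = list(background)
        if labels[i] == 1:
            hits = rng.random(WINDOW_LEN) < force_prob
            for x, c in enumerate(motif.consensus):
                if c != WILDCARD and hits[x]:
                    chars[x] = c
        chars[CENTER] = motif.central
        sequences.append("".join(chars))

    ptm_names = [target_ptm] + [f"helper{k}" for k in range(1, network.n_ptms)]
    A = np.zeros((n, network.n_ptms), dtype=np.int8)
    if network.target_included:
        A[: n_pos, 0] = 1
    if network.n_ptms > 1:
        probs = np.where(labels == 1, network.co_occurrence_prob, network.background_prob)
        A[:, 1:] = rng.random((n, network.n_ptms - 1)) < probs[:, None]

    width = len(str(n))
    proteins, windows, sites = [], [], []
    for i, seq in enumerate(sequences):
        pid = f"syn{i:0{width}d}"
        proteins.append(ProteinRecord(pid, seq))
        windows.append(PeptideWindow(f"{pid}:{CENTER + 1}", seq))
        annotations = frozenset(
            name for j, name in enumerate(ptm_names) if A[i, j]
        )
        sites.append(
            SiteAnnotation(pid, CENTER + 1, motif.central, annotations, int(labels[i]))
        )

    site_ids = [w.site_id for w in windows]
    return SyntheticDataset(
        proteins=proteins,
        windows=windows,
        sites=sites,
        profiles=InteractionProfileMatrix(site_ids, ptm_names, A),
        data=LabeledDataset(site_ids, labels, target_ptm),
    )


#: The three kernel configurations compared in a sweep.
SWEEP_CONFIGS = {
    "sequence_only": (1.0, 0.0),
    "gip_only": (0.0, 1.0),
    "combined": (0.5, 0.5),
}


def signal_sweep(
    strengths: Sequence[tuple[float, float]],
    n: int,
    seed: int,
    folds: int = 10,
    repeats: int = 1,
    gamma: float = 0.001,
    network: NetworkSpec | None = None,
    consensus: str | None = None,
) -> pd.DataFrame:
    """Mean CV AUC per signal strength for each kernel configuration.

    ``strengths`` is a list of (match_prob, co_occurrence_prob) pairs;
    ``n`` sites are generated per strength (half positive).  Returns a
    tidy frame with one row per strength and one AUC column per kernel
    configuration.
    """
    if not strengths:
        raise ValueError("strengths must be non-empty")
    base_network = network or NetworkSpec()
    consensus = consensus or full_consensus("S")
    rows = []
    for match_prob, co_prob in strengths:
        motif = MotifSpec(consensus=consensus, match_prob=match_prob)
        net = NetworkSpec(
            n_ptms=base_network.n_ptms,
            co_occurrence_prob=max(co_prob, base_network.background_prob),
            background_prob=base_network.background_prob,
            target_included=base_network.target_included,
        )
        ds = generate_dataset(n // 2, n - n // 2, motif, net, seed)
        row: dict[str, float] = {
            "match_prob": match_prob,
            "co_occurrence_prob": co_prob,
        }
        for name, betas in SWEEP_CONFIGS.items():
            result = run_cv(
                ds.windows,
                ds.profiles,
                ds.data,
                KernelConfig(gamma=gamma, betas=betas),
                ModelParams(),
                folds=folds,
                repeats=repeats,
                seed=seed,
            )
            row[f"auc_{name}"] = result.averaged.auc
        rows.append(row)
    return pd.DataFrame(rows)
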