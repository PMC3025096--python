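"""Target-decoy false-discovery-rate estimation for peptide-spectrum matches.

The estimator follows the separate-decoy-search design: the same spectra are
searched once against the target database and once against a decoy database
of reversed or shuffled sequences, and the FDR at a score threshold t is

    FDR(t) = #{decoy PSMs with score > t} / #{target PSMs with score > t}

with a strict inequality at the threshold. ``threshold_for_fdr`` inverts this
to find the most permissive score cut achieving a requested FDR.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DECOY_PREFIX = "DECOY_"


@dataclass(frozen=True)
class PSM:
    """One scored peptide-spectrum match."""

    peptide: str
    score: float
    is_decoy: bool
    run_id: str = ""


class PSMTable:
    """A collection of target and decoy PSMs."""

    def __init__(self, psms: Sequence[PSM]):
        self.psms = list(psms)
        for p in self.psms:
            if not np.isfinite(p.score):
                raise ValueError(f"non-finite score for peptide {p.peptide!r}")

    def __len__(self) -> int:
        return len(self.psms)

    @property
    def target_scores(self) -> np.ndarray:
        return np.array([p.score for p in self.psms if not p.is_decoy], dtype=float)

    @property
    def decoy_scores(self) -> np.ndarray:
        return np.array([p.score for p in self.psms if p.is_decoy], dtype=float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PSMTable":
        return cls([
            PSM(str(r.peptide), float(r.score), bool(r.is_decoy),
                str(getattr(r, "run_id", "")))
            for r in df.itertuples(index=False)
        ])

    @classmethod
    def read_tsv(cls, source) -> "PSMTable":
        return cls.from_frame(pd.read_csv(source, sep="\t", comment="#"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"peptide": p.peptide, "score": p.score,
              "is_decoy": int(p.is_decoy), "run_id": p.run_id} for p in self.psms]
        )


class UndefinedFDRError(ValueError):
    """Raised when no target PSM passes the threshold (FDR has no denominator)."""


class UnreachableFDRError(ValueError):
    """Raised when no score cut achieves the requested FDR."""


def generate_decoys(proteins: dict[str, str], mode: str = "reverse",
                    seed: Optional[int] = None) -> dict[str, str]:
    """Build one decoy per target protein, same length and residue composition.

    ``reverse`` flips each sequence (deterministic); ``shuffle`` permutes it
    with a seeded RNG. Decoy accessions carry the ``DECOY_`` prefix.
    """
    if not proteins:
        raise ValueError("empty protein set")
    if mode not in {"reverse", "shuffle"}:
        raise ValueError(f"unknown decoy mode {mode!r}")
    if mode == "shuffle" and seed is None:
        raise ValueError("shuffle mode requires a seed")
    rng = random.Random(seed)
    decoys = {}
    for acc, seq in proteins.items():
        if mode == "reverse":
            decoy = seq[::-1]
        else:
            chars = list(seq)
            rng.shuffle(chars)
            decoy = "".join(chars)
        decoys[DECOY_PREFIX + acc] = decoy
    return decoys


def fdr_at_threshold(psms: PSMTable, threshold: float) -> float:
    """Decoy-based FDR estimate among PSMs scoring strictly above ``threshold``."""
    n_targets = int(np.sum(psms.target_scores > threshold))
    n_decoys = int(np.sum(psms.decoy_scores > threshold))
    if n_targets == 0:
        raise UndefinedFDRError(
            f"no target PSM passes threshold {threshold}; FDR undefined")
    return n_decoys / n_targets


def threshold_for_fdr(psms: PSMTable, alpha: float) -> float:
    """Smallest observed target score whose passing set achieves FDR <= alpha.

    Candidate thresholds are the observed target scores; "passing" at
    candidate t means score >= t (i.e. the strict cut sits just below t).
    Ties resolve toward the smaller score, hence the larger passing set.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    targets = np.sort(psms.target_scores)
    if targets.size == 0:
        raise UndefinedFDRError("no target PSMs")
    decoys = psms.decoy_scores
    for t in targets:  # ascending: first achieving cut is the most permissive
        n_t = int(np.sum(targets >= t))
        n_d = int(np.sum(decoys >= t))
        if n_d / n_t <= alpha:
            return float(t)
    raise UnreachableFDRError(f"no score cut achieves FDR <= {alpha}")


def fdr_report(psms: PSMTable, threshold: float) -> dict:
    """Threshold, passing counts and FDR as a JSON-ready mapping."""
    n_targets = int(np.sum(psms.target_scores > threshold))
    n_decoys = int(np.sum(psms.decoy_scores > threshold))
    report = {
        "threshold": threshold,
        "n_targets_passing": n_targets,
        "n_decoys_passing": n_decoys,
        "fdr": (n_decoys / n_targets) if n_targets else None,
    }
    return report
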