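"""Expression normalization and reaction-level evidence scoring.

Raw read counts are normalized to transcripts per million (TPM) using gene
lengths, averaged over the samples of a cell type, and mapped onto reactions
through GPR rules (AND=min, OR=max).  A reaction is called *expressed* when
its evidence score reaches the cutoff (default 1 TPM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gpr import GPRScore, evaluate_gpr
from .model import MetabolicModel

__all__ = ["tpm_normalize", "mean_expression", "EvidenceTable"]

Vector = Union[Mapping[str, float], pd.Series]


def _as_series(x: Vector, name: str) -> pd.Series:
    s = pd.Series(x, dtype=float) if not isinstance(x, pd.Series) else x.astype(float)
    if s.empty:
        raise ValueError(f"{name} is empty")
    return s


def tpm_normalize(counts: Vector, lengths: Vector) -> pd.Series:
    """TPM_g = (count_g/length_g) / sum_h(count_h/length_h) * 1e6.

    Lengths are transcript lengths in bp and must be positive; counts must
    be nonnegative with at least one nonzero.  The result sums to 1e6
    (within 1e-6 relative).
    """
    c = _as_series(counts, "counts")
    l = _as_series(lengths, "lengths").reindex(c.index)
    if l.isna().any():
        missing = list(l.index[l.isna()])[:5]
        raise ValueError(f"missing gene lengths for {missing}")
    if (l <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (c < 0).any():
        raise ValueError("counts must be >= 0")
    rate = c / l
    total = rate.sum()
    if total <= 0:
        raise ValueError("all-zero counts: TPM undefined")
    return rate / total * 1e6


def mean_expression(samples: Union[pd.DataFrame, Sequence[Vector]]) -> pd.Series:
    """Arithmetic per-gene mean over the samples of one cell type.

    ``samples`` is a genes x samples DataFrame (already TPM) or a sequence
    of per-sample gene->TPM vectors sharing the same gene set.
    """
    if isinstance(samples, pd.DataFrame):
        if samples.shape[1] == 0:
            raise ValueError("need at least one sample")
        return samples.mean(axis=1)
    vecs = [_as_series(s, "sample") for s in samples]
    if not vecs:
        raise ValueError("need at least one sample")
    genes = set(vecs[0].index)
    for i, v in enumerate(vecs[1:], start=2):
        if set(v.index) != genes:
            raise ValueError(f"sample {i} gene set differs from sample 1")
    return pd.concat(vecs, axis=1).mean(axis=1)


@dataclass
class EvidenceTable:
    """Per-reaction expression evidence.

    ``scores`` maps reaction id -> evidence (GPR-aggregated mean TPM), or
    None for reactions without a GPR (spontaneous/transport): those carry no
    evidence and are never removed for lack of it.
    """

    scores: Dict[str, Optional[float]]
    cutoff: float = 1.0

    def __post_init__(self) -> None:
        if not (self.cutoff > 0):
            raise ValueError("cutoff must be > 0")
        for rid, s in self.scores.items():
            if s is not None and not (s >= 0):
                raise ValueError(f"evidence for {rid!r} must be >= 0, got {s!r}")

    def is_expressed(self, rxn_id: str) -> bool:
        s = self.scores.get(rxn_id)
        return s is not None and s >= self.cutoff

    def is_neutral(self, rxn_id: str) -> bool:
        return self.scores.get(rxn_id) is None

    @classmethod
    def from_expression(
        cls,
        model: MetabolicModel,
        mean_tpm: Vector,
        cutoff: float = 1.0,
    ) -> "EvidenceTable":
        """Score every reaction of the model from mean gene TPM.

        Genes absent from the expression table score 0 (unmeasured is
        treated as unexpressed).
        """
        tpm = _as_series(mean_tpm, "mean_tpm")
        gscore = GPRScore(gene_scores=tpm.to_dict())
        scores: Dict[str, Optional[float]] = {}
        for rxn in model.reactions:
            scores[rxn.id] = evaluate_gpr(rxn.gpr, gscore)
        return cls(scores=scores, cutoff=cutoff)
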