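"""Reporter-metabolite scoring and metabolite-set over-representation.

Reporter metabolite analysis flags metabolites around which transcription
changes concentrate: each gene's differential-expression p-value is mapped
to Z = Phi^-1(1 - p); a metabolite's raw score aggregates the Z of the
distinct genes found in the GPRs of its producing/consuming reactions,

    z_raw(m) = (1/sqrt(k)) * sum_{g in neighborhood(m)} Z_g,

and is corrected against a size-matched background: for every occurring
neighborhood size k, ``n_background`` random k-subsets of the scored genes
yield mu_k and sigma_k, and z_corr = (z_raw - mu_k)/sigma_k with upper-tail
p = 1 - Phi(z_corr).  Currency metabolites (ATP, NAD(P)(H), CO2, ...) are
excluded by a configurable blocklist; compartments can be scored separately
(default) or pooled.

Over-representation of a reporter set in pathway metabolite sets uses the
upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import MetabolicModel

__all__ = [
    "DEFAULT_CURRENCY",
    "ReporterScore",
    "gene_p_to_z",
    "metabolite_neighborhoods",
    "reporter_metabolites",
    "ora_hypergeometric",
]

#: base names excluded from reporter scoring (cofactors and small inorganics)
DEFAULT_CURRENCY = frozenset(
    {"atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "co2", "o2", "h2o", "pi", "h", "coa"}
)

_PCLIP = (1e-15, 1.0 - 1e-15)


@dataclass(frozen=True)
class ReporterScore:
    metabolite: str
    k: int  # number of distinct scored neighbor genes
    z_raw: float
    z_corrected: float
    p: float


def gene_p_to_z(pvalues: Mapping[str, float]) -> Dict[str, float]:
    """Z_g = Phi^-1(1 - p_g); p clamped into [1e-15, 1-1e-15]."""
    out: Dict[str, float] = {}
    for gene, p in pvalues.items():
        try:
            p = float(p)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric p-value for gene {gene!r}: {p!r}") from exc
        if p != p:
            raise ValueError(f"NaN p-value for gene {gene!r}")
        p = min(max(p, _PCLIP[0]), _PCLIP[1])
        out[gene] = float(stats.norm.isf(p))
    return out


def _met_base(met_id: str) -> str:
    return met_id.split("[", 1)[0]


def metabolite_neighborhoods(
    model: MetabolicModel,
    scored_genes: Set[str],
    currency: frozenset = DEFAULT_CURRENCY,
    pool_compartments: bool = False,
) -> Dict[str, frozenset]:
    """Metabolite -> distinct scored genes of its adjacent reactions.

    Adjacency means the metabolite is produced or consumed by the reaction;
    each gene counts once per metabolite regardless of how many adjacent
    reactions carry it.  Currency metabolites and coupling pseudo-species
    are skipped.  With ``pool_compartments`` the neighborhoods of one base
    metabolite across compartments are unioned under the base name.
    """
    nbhd: Dict[str, set] = {}
    for rxn in model.reactions:
        genes = rxn.genes & scored_genes
        if not genes:
            continue
        for met_id in rxn.stoichiometry:
            base = _met_base(met_id)
            if base.lower() in currency or met_id.startswith("CPL_"):
                continue
            key = base if pool_compartments else met_id
            nbhd.setdefault(key, set()).update(genes)
    return {k: frozenset(v) for k, v in nbhd.items()}


def reporter_metabolites(
    model: MetabolicModel,
    gene_z: Mapping[str, float],
    n_background: int = 10000,
    seed: int = 0,
    currency: frozenset = DEFAULT_CURRENCY,
    pool_compartments: bool = False,
) -> List[ReporterScore]:
    """Score reporter metabolites; sorted by ascending p (ties by id).

    Metabolites with no scored neighbor genes are omitted.  Deterministic
    given the seed.  With sigma_k = 0 (degenerate background, e.g. all gene
    Z equal) the corrected score is defined as 0.
    """
    scored_genes = set(gene_z)
    if not scored_genes & set(model.genes):
        raise ValueError("no gene shared between the Z table and the model GPRs")
    nbhd = metabolite_neighborhoods(model, scored_genes, currency, pool_compartments)
    if not nbhd:
        return []
    zvec = pd.Series(gene_z, dtype=float)
    gene_ids = np.array(sorted(scored_genes))
    zarr = zvec.reindex(gene_ids).to_numpy()
    rng = np.random.default_rng(seed)
    sizes = sorted({len(g) for g in nbhd.values()})
    background: Dict[int, Tuple[float, float]] = {}
    for k in sizes:
        if k > len(gene_ids):
            background[k] = (float("nan"), float("nan"))
            continue
        draws = np.empty(n_background)
        # vectorized sampling without replacement: argpartition over uniforms
        u = rng.random((n_background, len(gene_ids)))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k]
        draws = zarr[idx].sum(axis=1) / np.sqrt(k)
        background[k] = (float(draws.mean()), float(draws.std(ddof=0)))
    out: List[ReporterScore] = []
    for met in sorted(nbhd):
        genes = nbhd[met]
        k = len(genes)
        z_raw = float(sum(gene_z[g] for g in genes) / np.sqrt(k))
        mu, sigma = background[k]
        z_corr = 0.0 if not sigma or sigma != sigma else (z_raw - mu) / sigma
        p = float(np.clip(stats.norm.sf(z_corr), _PCLIP[0], _PCLIP[1]))
        out.append(ReporterScore(metabolite=met, k=k, z_raw=z_raw, z_corrected=float(z_corr), p=p))
    out.sort(key=lambda r: (r.p, r.metabolite))
    return out


def ora_hypergeometric(
    reporters: Set[str],
    pathways: Mapping[str, frozenset],
    universe: Set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of reporters per pathway.

    p = P(overlap >= observed | |universe|, |pathway|, |reporters|); zero
    overlap gives p = 1.  Returns a DataFrame (pathway, overlap, size, p,
    significant) sorted by p.  Pathway members outside the universe are
    ignored; reporters must lie within the universe.
    """
    if not universe:
        raise ValueError("empty metabolite universe")
    stray = set(reporters) - set(universe)
    if stray:
        raise ValueError(f"reporters outside the universe: {sorted(stray)[:5]}")
    M = len(universe)
    n = len(reporters)
    rows = []
    for name in sorted(pathways):
        members = set(pathways[name]) & set(universe)
        K = len(members)
        obs = len(members & reporters)
        # P(X >= obs) with X ~ Hypergeom(M, K, n)
        p = 1.0 if obs == 0 else float(stats.hypergeom.sf(obs - 1, M, K, n))
        rows.append({"pathway": name, "overlap": obs, "size": K, "p": p})
    df = pd.DataFrame(rows).sort_values(["p", "pathway"]).reset_index(drop=True)
    df["significant"] = df["p"] < alpha
    return df
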