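"""Count-table characterization: how zero-inflated and overdispersed is
each taxon, and how do these properties change with taxonomic rank.

Per taxon, the ZINB moment system

    E[Y]   = (1 - phi) * mu
    Var[Y] = (1 - phi) * mu * (1 + mu/theta + phi*mu)
    P(0)   = phi + (1 - phi) * (theta/(theta + mu))**theta

is solved for (phi, mu, theta) by matching the sample mean, variance and
zero fraction (mu and 1/theta are eliminated analytically, leaving a
bracketed scalar root-solve in phi).  The module also provides the
standard preprocessing steps: rarefaction to a fixed depth, a
minimum-total-count filter, and aggregation of counts to coarser
taxonomic ranks from SINTAX-style lineage strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TaxonCharacterization",
    "rarefy",
    "filter_low_abundance",
    "estimate_taxon_zinb_moments",
    "parse_sintax_lineage",
    "aggregate_to_rank",
    "characterize_cohort",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "asv")
_RANK_PREFIX = {"d": "domain", "p": "phylum", "c": "class", "o": "order", "f": "family", "g": "genus"}

#: default zero-inflation call threshold on phi_hat (package choice, configurable)
PHI_FLAG_THRESHOLD = 0.05
#: overdispersion call threshold on 1/theta_hat
OVERDISPERSION_THRESHOLD = 10.0


@dataclass(frozen=True)
class TaxonCharacterization:
    """Moment-based ZINB characterization of one taxon's counts."""

    taxon: str
    mean: float
    sd: float
    zero_fraction: float
    phi_hat: float
    inv_theta_hat: float
    inv_theta_nb_hat: float
    zero_inflated: bool


def rarefy(
    counts: pd.DataFrame, depth: int = 5000, seed: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Subsample each sample (column) without replacement to ``depth`` reads.

    Samples whose library size is below ``depth`` are dropped; their ids
    are returned alongside the rarefied table.  Each retained column is
    a multivariate-hypergeometric draw, so column sums equal ``depth``
    exactly and no cell exceeds its original count.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    kept, dropped = [], []
    out = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(sample)
            continue
        out[sample] = rng.multivariate_hypergeometric(col.astype(np.int64), depth)
        kept.append(sample)
    rare = pd.DataFrame(out, index=counts.index, columns=kept, dtype=np.int64)
    return rare, dropped


def filter_low_abundance(counts: pd.DataFrame, min_total: int) -> pd.DataFrame:
    """Drop taxa (rows) whose cohort-wide total is strictly below ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = counts.sum(axis=1)
    return counts.loc[totals >= min_total]


def _nb_zero_prob(mu: float, inv_theta: float) -> float:
    """P(Y=0) of NB(mu, theta=1/inv_theta); Poisson limit at inv_theta=0."""
    if inv_theta <= 1e-12:
        return float(np.exp(-mu))
    theta = 1.0 / inv_theta
    return float(np.exp(theta * (np.log(theta) - np.log(theta + mu))))


def estimate_taxon_zinb_moments(
    y: np.ndarray,
    taxon: str = "",
    phi_threshold: float = PHI_FLAG_THRESHOLD,
) -> TaxonCharacterization:
    """Estimate (phi, mu, 1/theta) for one taxon by three-moment matching.

    Eliminating mu = m/(1-phi) and 1/theta = (v/m - 1)/mu - phi from the
    mean/variance equations leaves a single monotone equation in phi for
    the zero fraction, solved by bracketed bisection on [0, p0]; phi_hat
    is clamped to [0, 1] and 1/theta estimates to [0, inf).  The NB-part
    dispersion ``inv_theta_nb_hat`` re-matches moments after removing
    ``floor(phi_hat * n)`` zeros (the estimated extra zeros).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not np.any(y > 0):
        raise ValueError("all-zero taxon: moments are unidentifiable")
    m = float(y.mean())
    v = float(y.var(ddof=1))
    if v == 0:
        raise ValueError("zero-variance taxon: moments are unidentifiable")
    p0 = float(np.mean(y == 0))

    def inv_theta_of(phi: float) -> float:
        mu = m / (1.0 - phi)
        return (v / m - 1.0) / mu - phi

    def f(phi: float) -> float:
        mu = m / (1.0 - phi)
        it = max(inv_theta_of(phi), 0.0)
        return phi + (1.0 - phi) * _nb_zero_prob(mu, it) - p0

    if p0 == 0.0 or f(0.0) >= 0.0:
        # the count component alone already explains the observed zeros
        phi_hat = 0.0
    else:
        hi = min(p0, 1.0 - 1e-9)
        phi_hat = float(optimize.brentq(f, 0.0, hi, xtol=1e-8))
    phi_hat = min(max(phi_hat, 0.0), 1.0)
    inv_theta_hat = max(inv_theta_of(phi_hat), 0.0)

    n_extra = int(np.floor(phi_hat * n))
    y_nb = np.sort(y)[n_extra:] if n_extra > 0 else y
    if np.any(y_nb > 0) and y_nb.size >= 2:
        m2, v2 = float(y_nb.mean()), float(y_nb.var(ddof=1))
        inv_theta_nb = max((v2 - m2) / max(m2**2, 1e-12), 0.0)
    else:
        inv_theta_nb = 0.0

    return TaxonCharacterization(
        taxon=taxon,
        mean=m,
        sd=float(np.sqrt(v)),
        zero_fraction=p0,
        phi_hat=phi_hat,
        inv_theta_hat=inv_theta_hat,
        inv_theta_nb_hat=inv_theta_nb,
        zero_inflated=bool(phi_hat > phi_threshold),
    )


def parse_sintax_lineage(lineage: str) -> dict[str, str]:
    """Parse a SINTAX-style lineage string ``d:...,p:...,...,g:...``."""
    out: dict[str, str] = {}
    for part in str(lineage).split(","):
        part = part.strip()
        if not part or ":" not in part:
            continue
        prefix, name = part.split(":", 1)
        rank = _RANK_PREFIX.get(prefix.strip().lower())
        if rank and name.strip():
            out[rank] = name.strip()
    return out


def aggregate_to_rank(
    counts: pd.DataFrame, taxonomy: pd.Series, rank: str
) -> pd.DataFrame:
    """Sum counts over taxa sharing the same label at ``rank``.

    ``taxonomy`` maps taxon id to a SINTAX lineage string.  Taxa whose
    lineage is unassigned at ``rank`` are pooled into "unclassified";
    taxa missing from ``taxonomy`` entirely are an error.  ``rank="asv"``
    is the identity.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    if rank == "asv":
        return counts.copy()
    missing = [t for t in counts.index if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxa missing from the lineage table: {missing}")
    labels = [
        parse_sintax_lineage(taxonomy.loc[t]).get(rank, "unclassified") for t in counts.index
    ]
    return counts.groupby(pd.Index(labels, name=rank), sort=False).sum()


def characterize_cohort(
    counts: pd.DataFrame,
    phi_threshold: float = PHI_FLAG_THRESHOLD,
    overdispersion_threshold: float = OVERDISPERSION_THRESHOLD,
) -> dict:
    """Characterize every taxon of a (filtered) count table.

    Returns a dict with the per-taxon table and cohort-level summaries:
    fraction of taxa flagged zero-inflated, mean phi among the flagged
    taxa, and the fraction with ``1/theta_hat`` above the
    overdispersion threshold.  Taxa whose moments are unidentifiable
    (all-zero or constant) are skipped and counted.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    rows = []
    skipped = 0
    for taxon in counts.index:
        y = counts.loc[taxon].to_numpy()
        try:
            c = estimate_taxon_zinb_moments(y, taxon=str(taxon), phi_threshold=phi_threshold)
        except ValueError:
            skipped += 1
            continue
        rows.append(c.__dict__)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no taxon had identifiable moments")
    flagged = table["zero_inflated"]
    summary = {
        "n_taxa": int(len(table)),
        "n_skipped": skipped,
        "zero_inflated_fraction": float(flagged.mean()),
        "mean_phi_zero_inflated": float(table.loc[flagged, "phi_hat"].mean())
        if flagged.any()
        else float("nan"),
        "overdispersed_fraction": float(
            (table["inv_theta_hat"] > overdispersion_threshold).mean()
        ),
    }
    return {"per_taxon": table, "summary": summary}
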