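"""Hypergeometric enrichment with Bonferroni correction.

Two granularities are supported:

* protein-level: presence/absence of a feature (e.g. a protease
  recognition motif in a given window) in a protein sample versus a
  background proteome, tested with the upper-tail hypergeometric
  probability P(X >= k) for k feature-positive proteins in a sample of n
  drawn without replacement from N background proteins of which K carry
  the feature;
* residue-level: the K+R composition of a single window versus the
  residue composition of a background scope, one test per protein and
  window size, Bonferroni-corrected over the whole family
  (proteins x window sizes).

When only a background *proportion* is known (no countable background),
the hypergeometric test degrades to a binomial test and the result is
flagged as proportion-mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from scipy import stats as sps

from .annotations import BackgroundSet, DomainAnnotation, ProteinRecord
from .features import ChargeProfile

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "fold_enrichment",
    "bonferroni",
    "protein_level_enrichment",
    "residue_level_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One enrichment test with the counts that produced it.

    ``k``/``n`` are the sample hits and sample size; ``K``/``N`` the
    background hits and background size (``None`` in proportion mode,
    where only ``background_proportion`` is known).  ``fold`` is
    (k/n)/(K/N); ``p_raw`` the upper-tail probability and ``p_adjusted``
    its Bonferroni correction, capped at 1.
    """

    feature: str
    window: str
    k: int
    n: int
    K: Optional[int]
    N: Optional[int]
    fold: float
    p_raw: float
    p_adjusted: float
    background: str = ""
    mode: str = "hypergeometric"
    background_proportion: Optional[float] = None
    protein_id: Optional[str] = None
    skipped: Optional[str] = None


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) drawing n without replacement from N with K successes."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"invalid hypergeometric configuration k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # scipy parameterisation: M=N population, n=K successes, N=n draws
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, background_proportion: float) -> float:
    """(k/n) / background_proportion -- e.g. (38, 57, 0.50) -> 1.33."""
    if n <= 0:
        raise ValueError("sample size must be positive")
    if background_proportion <= 0:
        raise ValueError("background proportion must be positive")
    return (k / n) / background_proportion


def bonferroni(p_values: Sequence[float], family_size: Optional[int] = None
               ) -> list[float]:
    """Multiply each p by the family size, capped at 1 (order preserved)."""
    m = len(p_values) if family_size is None else family_size
    if m < len(p_values):
        raise ValueError("family size smaller than the number of tests")
    return [min(1.0, p * m) for p in p_values]


def protein_level_enrichment(
    sample: Sequence[tuple[ProteinRecord, Optional[DomainAnnotation]]],
    background: BackgroundSet | float,
    feature: Callable[[ProteinRecord, Optional[DomainAnnotation]], bool],
    feature_name: str = "feature",
    window_label: str = "full",
    family_size: int = 1,
) -> EnrichmentResult:
    """Presence/absence enrichment of a feature in a protein sample.

    ``feature`` is a predicate evaluated on each (record, annotation)
    pair of the sample and, in countable mode, on each background record
    (with the background's TMD spans wrapped into a minimal annotation
    when available).  ``background`` may instead be a plain proportion,
    in which case a binomial test is used and the result flagged
    proportion-mode.
    """
    n = len(sample)
    k = sum(bool(feature(rec, ann)) for rec, ann in sample)

    if isinstance(background, float):
        p0 = background
        p_raw = 1.0 if k == 0 else float(sps.binom.sf(k - 1, n, p0))
        fold = (k / n) / p0 if n else float("nan")
        return EnrichmentResult(
            feature=feature_name, window=window_label, k=k, n=n,
            K=None, N=None, fold=fold, p_raw=p_raw,
            p_adjusted=min(1.0, p_raw * family_size),
            background="proportion", mode="binomial-proportion",
            background_proportion=p0,
        )

    from .annotations import DomainAnnotation as _DA

    needs_tmd = window_label != "full"
    if needs_tmd and background.label != "membrane_proteome":
        raise ValueError(
            f"window {window_label!r} is TMD-anchored but background "
            f"{background.label!r} carries no TMD spans")
    K = 0
    for rec in background.records:
        ann = None
        tmds = background.tmds.get(rec.id)
        if tmds:
            # minimal annotation: TFFD placement unknown for backgrounds,
            # so TMD-anchored windows use symmetric flanks via tmd_plus_flank
            ann = _DA(protein_id=rec.id, tffd=(1, 1), tmds=list(tmds))
        K += bool(feature(rec, ann))
    N = len(background)
    fold = (k / n) / (K / N) if n and K else (0.0 if k == 0 else float("inf"))
    mode = "hypergeometric"
    K_pop, N_pop = K, N
    if k > K or n > N:
        # sample is disjoint from the background: pool it into the
        # population so the urn model is well defined
        K_pop, N_pop = K + k, N + n
        mode = "hypergeometric (sample pooled into population)"
    p_raw = hypergeom_upper_tail(k, n, K_pop, N_pop)
    return EnrichmentResult(
        feature=feature_name, window=window_label, k=k, n=n, K=K, N=N,
        fold=fold, p_raw=p_raw, p_adjusted=min(1.0, p_raw * family_size),
        background=background.label, mode=mode,
    )


def residue_level_enrichment(
    profile: ChargeProfile,
    window_k: int,
    background_kr: int,
    background_total: int,
    family_size: int = 1,
    background_label: str = "proteome",
) -> EnrichmentResult:
    """K/R overrepresentation of one protein's flank window.

    ``k`` = K+R residues in the window, ``n`` = clipped window length,
    tested against ``background_kr`` K/R residues among
    ``background_total`` background residues.  The Bonferroni
    ``family_size`` is the number of proteins tested times the number of
    window sizes.  Empty windows are skipped with a reason.
    """
    kc, rc, length = profile.flank(window_k)
    k = kc + rc
    if length == 0:
        return EnrichmentResult(
            feature="KR", window=f"flank_tffd_side({window_k})",
            k=0, n=0, K=background_kr, N=background_total,
            fold=float("nan"), p_raw=1.0, p_adjusted=1.0,
            background=background_label, protein_id=profile.protein_id,
            skipped="empty window (overlap-class protein or fully clipped)",
        )
    p_raw = hypergeom_upper_tail(k, length, background_kr, background_total)
    bg_prop = background_kr / background_total
    fold = (k / length) / bg_prop if bg_prop > 0 else float("inf")
    return EnrichmentResult(
        feature="KR", window=f"flank_tffd_side({window_k})",
        k=k, n=length, K=background_kr, N=background_total,
        fold=fold, p_raw=p_raw, p_adjusted=min(1.0, p_raw * family_size),
        background=background_label, protein_id=profile.protein_id,
    )


def flank_kr_background(background: BackgroundSet, k: int) -> tuple[int, int]:
    """Total (K+R, all) residue counts in the +/-k TMD flanks of a
    membrane background -- the sampling frame for residue-level tests.

    Background proteins have no TFFD, so both flanks of the first TMD are
    pooled (clipped at the sequence termini).
    """
    if background.label != "membrane_proteome":
        raise ValueError("flank background requires a membrane proteome")
    kr = total = 0
    for rec in background.records:
        tmd = background.tmds[rec.id][0]
        left = rec.sequence[max(0, tmd.start - 1 - k):tmd.start - 1]
        right = rec.sequence[tmd.end:tmd.end + k]
        for sub in (left, right):
            kr += sub.count("K") + sub.count("R")
            total += len(sub)
    return kr, total


def proteome_kr_background(background: BackgroundSet) -> tuple[int, int]:
    """Total (K+R, all) residue counts over a whole background proteome."""
    kr = total = 0
    for rec in background.records:
        kr += rec.sequence.count("K") + rec.sequence.count("R")
        total += len(rec.sequence)
    return kr, total
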