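"""Evidence integration: per-protein RIP-candidate reports and cohort summaries.

Each protein accumulates boolean evidence flags (protease recognition
sites, helix breakers and charged residues in/near the TMD, PTMs and
proteolytic N-termini between the TFFD and the TMD, topology, alternative
TMD-less transcripts) and is assigned a tier by an explicit decision
table:

* ``RIP-candidate``   -- cytosolic TFFD AND (a protease-site flag OR
  (a helix breaker in the TMD AND charged residues in the TMD or a
  significantly K/R-enriched flank));
* ``splicing-candidate`` -- an annotated TMD-lacking alternative
  transcript and no protease-site flag;
* ``RIP-possible``    -- any single RIP-consistent evidence flag;
* ``uninformative``   -- none of the above.

The table is a heuristic conjunction of topology with sequence/structure
evidence, not a calibrated probability; it is versioned in
:data:`TIER_RULES_VERSION` and every true flag carries provenance
(window, span, adjusted p) sufficient to recompute it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotations import DomainAnnotation, ProteinRecord
from .features import (
    ChargeProfile,
    TopologyClass,
    charge_profile,
    classify_topology,
    find_helix_breakers,
    proteolytic_nterm_near_tmd,
    ptm_between_tffd_and_tmd,
)
from .motifs import MotifCatalog, default_catalog, protein_has_motif

__all__ = ["CandidateReport", "build_report", "analyze_protein",
           "summarize_cohort", "TIERS"]

TIER_RULES_VERSION = "1.0"

TIERS = ("uninformative", "RIP-possible", "splicing-candidate", "RIP-candidate")

#: Flags that count as direct protease-site evidence in the decision
#: table.  The pan-rhomboid minimal consensus is deliberately excluded:
#: it matches the large majority of TMDs and has no discriminative value.
PROTEASE_SITE_FLAGS = (
    "s1p_site_exact", "s1p_site_degenerate", "rhomboid_site",
)

#: Flags treated as RIP-consistent evidence for the RIP-possible tier.
#: Topology (tffd_cytosolic) and NLS are context, not evidence, and the
#: splicing flag points away from proteolysis.
RIP_EVIDENCE_FLAGS = PROTEASE_SITE_FLAGS + (
    "helix_breaker_in_tmd", "kr_in_tmd", "kr_flank_enriched",
    "ptm_between_domains", "proteolytic_nterm_near_tmd",
)

ALL_FLAGS = RIP_EVIDENCE_FLAGS + (
    "pan_rhomboid_site", "tffd_cytosolic", "nls_present",
    "alt_transcript_lacking_tmd",
)

# Strength ranks used by the monotonicity contract: removing evidence may
# move a protein sideways between the two middle tiers but never upward.
TIER_RANK = {"uninformative": 0, "RIP-possible": 1,
             "splicing-candidate": 1, "RIP-candidate": 2}


@dataclass
class CandidateReport:
    """Evidence flags, provenance, and tier for one protein."""

    protein_id: str
    flags: dict[str, bool]
    tier: str
    provenance: dict[str, object] = field(default_factory=dict)
    topology: Optional[TopologyClass] = None


def assign_tier(flags: dict[str, bool]) -> str:
    """The decision table; a pure, total function of the flag set."""
    f = {name: bool(flags.get(name, False)) for name in ALL_FLAGS}
    protease = any(f[name] for name in PROTEASE_SITE_FLAGS)
    structural = f["helix_breaker_in_tmd"] and (
        f["kr_in_tmd"] or f["kr_flank_enriched"])
    if f["tffd_cytosolic"] and (protease or structural):
        return "RIP-candidate"
    if f["alt_transcript_lacking_tmd"] and not protease:
        return "splicing-candidate"
    if any(f[name] for name in RIP_EVIDENCE_FLAGS):
        return "RIP-possible"
    return "uninformative"


def build_report(protein_id: str, flags: dict[str, bool],
                 provenance: Optional[dict] = None,
                 topology: Optional[TopologyClass] = None) -> CandidateReport:
    """Assemble a report from precomputed flags.

    Unknown topology must be encoded as ``tffd_cytosolic=False`` (the
    conjunction then caps the protein at RIP-possible).
    """
    return CandidateReport(
        protein_id=protein_id,
        flags={name: bool(flags.get(name, False)) for name in ALL_FLAGS},
        tier=assign_tier(flags),
        provenance=provenance or {},
        topology=topology,
    )


def analyze_protein(record: ProteinRecord, annotation: DomainAnnotation,
                    catalog: Optional[MotifCatalog] = None,
                    kr_flank_enriched: Optional[bool] = None,
                    kr_flank_provenance: Optional[dict] = None,
                    flank_k: int = 20,
                    tmd_policy: str | int = "first") -> CandidateReport:
    """Run the sequence-level evidence scans for one protein.

    Protease-recognition motifs are scanned forward in the TMD plus
    ``flank_k``-residue flanks; helix motifs in the TMD in both
    orientations.  ``kr_flank_enriched`` is an upstream enrichment call
    (it needs a background); when ``None`` the annotation's significance
    flag is used.  Overlap-class proteins are reported with all scan
    flags false: they are excluded from feature scanning because a TMD
    inside the TFFD cannot be removed by proteolysis without destroying
    the domain.
    """
    if catalog is None:
        catalog = default_catalog()
    topo = classify_topology(annotation, tmd_policy="first")
    flags: dict[str, bool] = {}
    prov: dict[str, object] = {"tier_rules_version": TIER_RULES_VERSION}

    if topo.position_class != "overlap":
        def has(name: str, window: str = "tmd_plus_flank") -> bool:
            pat = catalog[name]
            return protein_has_motif(record, annotation, pat, window,
                                     k=flank_k, tmd_policy=tmd_policy)

        flags["s1p_site_exact"] = has("RRIL")
        flags["s1p_site_degenerate"] = has("S1P-degenerate")
        flags["rhomboid_site"] = (has("Rho1-NTL7") or has("Rho1-relaxed")
                                  or has("rhomboid-AarA-type")
                                  or has("rhomboid-compact"))
        flags["pan_rhomboid_site"] = has("pan-rhomboid")
        helix_hits = find_helix_breakers(record, annotation, catalog,
                                         tmd_policy=tmd_policy)
        flags["helix_breaker_in_tmd"] = bool(helix_hits)
        if helix_hits:
            prov["helix_breaker_hits"] = [
                (h.motif_name, h.start, h.end) for h in helix_hits]
        profile = charge_profile(record, annotation, tmd_policy="first")
        flags["kr_in_tmd"] = profile.kr_tmd > 0
        prov["kr_tmd"] = (profile.k_tmd, profile.r_tmd)
        flags["ptm_between_domains"] = bool(ptm_between_tffd_and_tmd(annotation))
        flags["proteolytic_nterm_near_tmd"] = proteolytic_nterm_near_tmd(annotation)
    else:
        prov["excluded"] = "overlap-class protein: feature scans skipped"

    if kr_flank_enriched is None:
        kr_flank_enriched = annotation.kr_flank_significant
    flags["kr_flank_enriched"] = bool(kr_flank_enriched)
    if kr_flank_provenance:
        prov["kr_flank"] = kr_flank_provenance
    flags["tffd_cytosolic"] = topo.tffd_side == "cytosolic"
    flags["nls_present"] = bool(annotation.nls_present)
    flags["alt_transcript_lacking_tmd"] = annotation.n_alt_transcripts > 0
    return build_report(record.id, flags, provenance=prov, topology=topo)


def summarize_cohort(annotations: Sequence[DomainAnnotation],
                     reports: Optional[Sequence[CandidateReport]] = None,
                     ) -> dict[str, object]:
    """Cohort-level counts and percentages.

    Works from annotation columns alone (position classes, topology,
    cytosolic-TFFD count, annotated helix breakers and K/R counts, PTMs,
    alternative transcripts); sequence-scan statistics (per-motif counts,
    tiers) are added when ``reports`` are supplied.  Percentages carry
    their denominator.
    """
    n = len(annotations)
    summary: dict[str, object] = {"n_proteins": n}
    if n == 0:
        summary.update({
            "position_class": {}, "topology": {}, "cytosolic_tffd": (0, 0),
            "helix_breaker_annotated": 0, "kr_in_tmd_annotated": 0,
            "kr_flank_significant": 0, "ptm_between_domains": 0,
            "alt_transcript": 0,
        })
        if reports is not None:
            summary["tiers"] = {}
            summary["motif_hits"] = {}
        return summary

    topo_classes = [classify_topology(a) for a in annotations]
    pos_counts: dict[str, int] = {}
    topo_counts: dict[str, int] = {}
    cytosolic = 0
    for tc in topo_classes:
        pos_counts[tc.position_class] = pos_counts.get(tc.position_class, 0) + 1
        topo_counts[tc.topology] = topo_counts.get(tc.topology, 0) + 1
        if tc.tffd_side == "cytosolic":
            cytosolic += 1
    summary["position_class"] = pos_counts
    summary["topology"] = topo_counts
    summary["cytosolic_tffd"] = (cytosolic, n)
    summary["cytosolic_tffd_pct"] = round(100.0 * cytosolic / n, 1)
    summary["helix_breaker_annotated"] = sum(
        1 for a in annotations if any(m for m in a.helix_motifs))
    summary["kr_in_tmd_annotated"] = sum(
        1 for a in annotations
        if a.kr_tmd is not None and sum(a.kr_tmd) > 0)
    summary["kr_flank_significant"] = sum(
        1 for a in annotations if a.kr_flank_significant)
    summary["ptm_between_domains"] = sum(
        1 for a in annotations
        if any(p.between_domains for p in a.ptms))
    summary["phosphorylated"] = sum(
        1 for a in annotations
        if any(p.kind == "phosphorylation" for p in a.ptms))
    summary["alt_transcript"] = sum(
        1 for a in annotations if a.n_alt_transcripts > 0)

    if reports is not None:
        tiers: dict[str, int] = {}
        motif_hits: dict[str, int] = {}
        for rep in reports:
            tiers[rep.tier] = tiers.get(rep.tier, 0) + 1
            for flag, value in rep.flags.items():
                if value:
                    motif_hits[flag] = motif_hits.get(flag, 0) + 1
        summary["tiers"] = tiers
        summary["flag_counts"] = motif_hits
    return summary
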