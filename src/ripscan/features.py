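"""TMD-anchored windows, charge profiling, helix breakers and topology.

The operations here resolve search windows around a transmembrane domain
(the TMD itself, the TMD plus k-residue flanks, or the k-residue flank on
the side facing the transcription-factor family domain), count positively
charged residues (K, R) inside them, locate helix-destabilising motifs in
the TMD, classify the TMD position relative to the TFFD (N, C or overlap)
and combine it with the type-I/II topology call to infer on which side of
the membrane the TFFD sits.  A TFFD on the cytosolic side is the
precondition for nuclear relocation after a single cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .annotations import DomainAnnotation, PTMRecord, ProteinRecord
from .motifs import MotifCatalog, MotifHit, default_catalog, scan_window

__all__ = [
    "SearchWindow",
    "ChargeProfile",
    "TopologyClass",
    "resolve_window",
    "charge_profile",
    "find_helix_breakers",
    "classify_topology",
    "ptm_between_tffd_and_tmd",
    "proteolytic_nterm_near_tmd",
]

WINDOW_LABELS = ("full", "tmd", "tmd_plus_flank", "flank_tffd_side")

#: Maximum distance (residues) from the TMD, on the TFFD side, at which a
#: proteolytically generated N-terminus is still called consistent with
#: regulated intramembrane proteolysis.
RIP_NTERM_PROXIMITY = 41


@dataclass(frozen=True)
class SearchWindow:
    """A resolved, clip-safe residue window (1-based inclusive).

    An empty window is encoded as ``end < start`` with ``length == 0``.
    """

    label: str
    start: int
    end: int
    k: Optional[int] = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def is_empty(self) -> bool:
        return self.end < self.start

    def __len__(self) -> int:
        return 0 if self.is_empty else self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class TopologyClass:
    """TMD position class, topology call, and inferred TFFD membrane side.

    position_class: "C" (TMD C-terminal of the TFFD), "N" (TMD N-terminal)
    or "overlap".  tffd_side is "cytosolic" for (C, II) or (N, I),
    "luminal" for (C, I) or (N, II), and "NA" otherwise (overlap class or
    missing topology call).
    """

    protein_id: str
    position_class: str
    topology: str
    tffd_side: str


@dataclass(frozen=True)
class ChargeProfile:
    """Lysine/arginine counts in the TMD and in TFFD-side flank windows."""

    protein_id: str
    k_tmd: int
    r_tmd: int
    tmd_length: int
    flanks: tuple[tuple[int, int, int, int], ...]
    # each flank entry: (window size k, K count, R count, clipped length)

    @property
    def kr_tmd(self) -> int:
        return self.k_tmd + self.r_tmd

    def flank(self, k: int) -> tuple[int, int, int]:
        """(K, R, clipped length) for the k-residue TFFD-side flank."""
        for kk, kc, rc, ln in self.flanks:
            if kk == k:
                return kc, rc, ln
        raise KeyError(f"no flank window of size {k}")


def _clip(start: int, end: int, length: Optional[int]) -> tuple[int, int]:
    start = max(1, start)
    if length is not None:
        end = min(length, end)
    return start, end


def resolve_window(annotation: DomainAnnotation, label: str,
                   k: Optional[int] = None,
                   tmd_policy: str | int = "first",
                   length: Optional[int] = None) -> SearchWindow:
    """Resolve a window label to concrete residue coordinates.

    * ``tmd`` -- the selected TMD span.
    * ``tmd_plus_flank`` -- TMD extended by ``k`` residues on both sides.
    * ``flank_tffd_side`` -- the ``k`` residues abutting the TMD on the
      side facing the TFFD, excluding the TMD itself.  For overlap-class
      proteins (TMD inside/overlapping the TFFD) there is no such flank
      and the defined-degenerate result is an empty window.
    * ``full`` -- the whole sequence (requires ``length``).

    Coordinates are clipped to ``[1, length]`` when ``length`` is given.
    """
    if label == "full":
        if length is None:
            raise ValueError("label 'full' requires the sequence length")
        return SearchWindow("full", 1, length)
    tmd = annotation.select_tmd(tmd_policy)
    if label == "tmd":
        s, e = _clip(tmd.start, tmd.end, length)
        return SearchWindow("tmd", s, e)
    if k is None:
        raise ValueError(f"label {label!r} requires a flank size k")
    if label == "tmd_plus_flank":
        s, e = _clip(tmd.start - k, tmd.end + k, length)
        return SearchWindow("tmd_plus_flank", s, e, k=k)
    if label == "flank_tffd_side":
        ts, te = annotation.tffd
        if te < tmd.start:  # TFFD strictly N-terminal of the TMD: left flank
            s, e = _clip(tmd.start - k, tmd.start - 1, length)
            if e >= s:
                return SearchWindow("flank_tffd_side", s, e, k=k)
        elif ts > tmd.end:  # TFFD strictly C-terminal: right flank
            s, e = _clip(tmd.end + 1, tmd.end + k, length)
            if e >= s:
                return SearchWindow("flank_tffd_side", s, e, k=k)
        # overlap class (or fully clipped): empty window
        return SearchWindow("flank_tffd_side", 1, 0, k=k)
    raise ValueError(f"unknown window label {label!r}")


def charge_profile(record: ProteinRecord, annotation: DomainAnnotation,
                   ks: Sequence[int] = (5, 10, 15, 20),
                   tmd_policy: str | int = "first") -> ChargeProfile:
    """Count K and R in the TMD and in each TFFD-side flank window.

    Clipped window lengths are recorded so that downstream enrichment
    tests use the correct sampling frame.
    """
    seq = record.sequence
    tmd_w = resolve_window(annotation, "tmd", tmd_policy=tmd_policy,
                           length=record.length)
    tmd_seq = seq[tmd_w.start - 1:tmd_w.end]
    flanks = []
    for k in ks:
        w = resolve_window(annotation, "flank_tffd_side", k=k,
                           tmd_policy=tmd_policy, length=record.length)
        sub = "" if w.is_empty else seq[w.start - 1:w.end]
        flanks.append((k, sub.count("K"), sub.count("R"), len(sub)))
    return ChargeProfile(
        protein_id=record.id,
        k_tmd=tmd_seq.count("K"),
        r_tmd=tmd_seq.count("R"),
        tmd_length=len(tmd_seq),
        flanks=tuple(flanks),
    )


def find_helix_breakers(record: ProteinRecord, annotation: DomainAnnotation,
                        catalog: Optional[MotifCatalog] = None,
                        tmd_policy: str | int = "first") -> list[MotifHit]:
    """Locate helix-destabilising motifs inside the TMD.

    Scans the helix catalog (NP, NxxP, PxxP, GxxN, PxxN, PN, GA) in both
    orientations; hits are deduplicated by (motif, span).
    """
    if catalog is None:
        catalog = default_catalog()
    hits: dict[tuple[str, int, int], MotifHit] = {}
    for tmd_index in (range(len(annotation.tmds)) if tmd_policy == "all"
                      else [tmd_policy]):
        w = resolve_window(annotation, "tmd", tmd_policy=tmd_index,
                           length=record.length)
        for pattern in catalog.helix_patterns:
            for orient in ("forward", "reverse"):
                for hit in scan_window(record, pattern, w.span, orient,
                                       window_label="tmd"):
                    hits.setdefault((hit.motif_name, hit.start, hit.end), hit)
    return sorted(hits.values(), key=lambda h: (h.start, h.motif_name))


def classify_topology(annotation: DomainAnnotation,
                      tmd_policy: str | int = "first") -> TopologyClass:
    """Classify TMD position (N/C/overlap) and infer the TFFD membrane side.

    Type I puts the C-terminus in the cytosol, type II the N-terminus.
    With a C-terminal TMD the TFFD is the N-terminal part, so (C, II) is
    cytosolic and (C, I) luminal; with an N-terminal TMD the assignment
    flips.  Overlap-class proteins get side "NA".
    """
    tmd = annotation.select_tmd(tmd_policy)
    ts, te = annotation.tffd
    if tmd.start > te:
        position = "C"
    elif tmd.end < ts:
        position = "N"
    else:
        position = "overlap"
    topo = tmd.topology
    if position == "C" and topo == "II":
        side = "cytosolic"
    elif position == "C" and topo == "I":
        side = "luminal"
    elif position == "N" and topo == "I":
        side = "cytosolic"
    elif position == "N" and topo == "II":
        side = "luminal"
    else:
        side = "NA"
    return TopologyClass(annotation.protein_id, position, topo, side)


def _between_interval(annotation: DomainAnnotation,
                      tmd_policy: str | int = "first"
                      ) -> Optional[tuple[int, int]]:
    """Open interval strictly between the TFFD and the TMD (or None)."""
    tmd = annotation.select_tmd(tmd_policy)
    ts, te = annotation.tffd
    if te < tmd.start:
        lo, hi = te + 1, tmd.start - 1
    elif tmd.end < ts:
        lo, hi = tmd.end + 1, ts - 1
    else:
        return None
    if hi < lo:
        return None
    return lo, hi


def ptm_between_tffd_and_tmd(annotation: DomainAnnotation,
                             tmd_policy: str | int = "first"
                             ) -> list[PTMRecord]:
    """PTMs positioned strictly between the TFFD and the TMD.

    Boundary residues belong to their domains.  PTMs without a known
    position are included only when they carry the annotated
    between-domains flag.  Overlap-class proteins yield an empty list.
    """
    interval = _between_interval(annotation, tmd_policy)
    out = []
    for p in annotation.ptms:
        if p.position is None:
            if p.between_domains:
                out.append(p)
        elif interval is not None and interval[0] <= p.position <= interval[1]:
            out.append(p)
    return out


def proteolytic_nterm_near_tmd(annotation: DomainAnnotation,
                               max_distance: int = RIP_NTERM_PROXIMITY,
                               tmd_policy: str | int = "first") -> bool:
    """True if a proteolytic N-terminus lies on the TFFD side of the TMD
    within ``max_distance`` residues -- the placement expected from a RIP
    cleavage event.

    A positioned N-terminus is checked directly; an unpositioned one
    counts only when annotated as between-domains and the TFFD-TMD gap on
    that side is itself within ``max_distance``.
    """
    tmd = annotation.select_tmd(tmd_policy)
    ts, te = annotation.tffd
    interval = _between_interval(annotation, tmd_policy)
    for p in annotation.ptms:
        if p.kind != "proteolytic N-terminus":
            continue
        if p.position is not None:
            if te < tmd.start:  # TFFD side is left of the TMD
                dist = tmd.start - p.position
            elif tmd.end < ts:
                dist = p.position - tmd.end
            else:
                continue
            if 0 < dist <= max_distance:
                return True
        elif p.between_domains and interval is not None:
            gap = interval[1] - interval[0] + 1
            if gap <= max_distance:
                return True
    return False
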