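"""Domain types and I/O for membrane-bound transcription factor (MB-TF) annotations.

An MB-TF carries both a transcription-factor family domain (TFFD) and at
least one transmembrane domain (TMD).  This module defines the in-memory
representation of a protein plus its domain organisation -- TFFD span, TMD
span(s) with hydrophobicity score and type-I/II topology call, subcellular
localisation labels, and post-translational modification (PTM) records --
and readers/writers for the plain-text formats the pipeline consumes:
protein FASTA and a per-protein annotation TSV.

All residue coordinates are 1-based and inclusive at both ends.
"""

from __future__ import annotations

import importlib.resources
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "TMDSpan",
    "PTMRecord",
    "DomainAnnotation",
    "BackgroundSet",
    "AnnotationError",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "load_table1_fixture",
]

#: The 20 standard residues; "X" is additionally accepted as an unknown residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Localisation labels understood by the annotation reader.
LOCALIZATION_LABELS = frozenset(
    {"nuc", "er", "pm", "golgi", "mt", "pl", "sec", "cyt"}
)

#: PTM kind abbreviations (Table-style shorthand -> long name).
PTM_KINDS = {
    "ph": "phosphorylation",
    "na": "N-terminal acetylation",
    "nt": "proteolytic N-terminus",
    "ng": "N-glycosylation",
    "ac": "lysine acetylation",
    "ro": "cysteine oxidation",
    "sm": "SUMOylation",
    "ub": "ubiquitination",
    "my": "myristoylation",
}
_PTM_ABBREV = {v: k for k, v in PTM_KINDS.items()}


class AnnotationError(ValueError):
    """Raised for malformed sequence or annotation input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier."""

    id: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise AnnotationError(
                f"record {self.id!r}: illegal residue(s) {sorted(bad)} "
                f"(allowed: 20 standard amino acids and X)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TMDSpan:
    """One predicted transmembrane segment.

    ``topology`` follows the single-pass convention: type I places the
    C-terminus in the cytosol, type II the N-terminus; ``NA`` means no
    confident call.  ``score`` is a mean-hydrophobicity score in [0, 1]
    (``None`` when unknown).
    """

    start: int
    end: int
    score: Optional[float] = None
    topology: str = "NA"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(f"invalid TMD span ({self.start}, {self.end})")
        if self.topology not in ("I", "II", "NA"):
            raise AnnotationError(f"invalid topology {self.topology!r}")
        n = self.end - self.start + 1
        if n < 12 or n > 40:
            warnings.warn(
                f"TMD span ({self.start}, {self.end}) has unusual length {n} "
                f"(typical transmembrane helices span 18-25 residues)",
                stacklevel=2,
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PTMRecord:
    """A post-translational modification, optionally positioned.

    ``between_domains`` marks modifications reported to fall between the
    TFFD and the TMD when the exact residue position is not available.
    """

    kind: str
    position: Optional[int] = None
    between_domains: bool = False

    def __post_init__(self) -> None:
        if self.kind not in PTM_KINDS.values():
            raise AnnotationError(f"unknown PTM kind {self.kind!r}")
        if self.position is not None and self.position < 1:
            raise AnnotationError(f"invalid PTM position {self.position}")


@dataclass
class DomainAnnotation:
    """Domain organisation of one MB-TF.

    ``kr_tmd``/``kr_flank`` hold externally annotated (lysine, arginine)
    counts for the first-listed TMD and its 20-residue TFFD-side flank;
    they are carried for fixture-only statistics and are ``None`` when the
    counts should be computed from sequence instead.
    """

    protein_id: str
    tffd: tuple[int, int]
    tmds: list[TMDSpan]
    name: str = ""
    nls_present: Optional[bool] = None
    localizations: frozenset[str] = frozenset()
    ptms: list[PTMRecord] = field(default_factory=list)
    helix_motifs: list[str] = field(default_factory=list)
    kr_tmd: Optional[tuple[int, int]] = None
    kr_flank: Optional[tuple[int, int]] = None
    kr_flank_significant: bool = False
    n_alt_transcripts: int = 0

    def __post_init__(self) -> None:
        if self.tffd[0] < 1 or self.tffd[1] < self.tffd[0]:
            raise AnnotationError(
                f"{self.protein_id}: invalid TFFD span {self.tffd}"
            )
        if not self.tmds:
            raise AnnotationError(
                f"{self.protein_id}: an MB-TF annotation needs at least one TMD"
            )

    def select_tmd(self, policy: str | int = "first") -> TMDSpan:
        """Pick one TMD under a selection policy ("first" or a 0-based index)."""
        if policy == "first":
            return self.tmds[0]
        if isinstance(policy, int):
            return self.tmds[policy]
        raise ValueError(f"unknown TMD selection policy {policy!r}")

    def iter_tmds(self, policy: str | int = "first") -> list[TMDSpan]:
        if policy == "all":
            return list(self.tmds)
        return [self.select_tmd(policy)]

    def validate_against(self, record: ProteinRecord) -> None:
        """Check every span fits inside the sequence."""
        n = record.length
        spans = [("TFFD", self.tffd)] + [("TMD", t.span) for t in self.tmds]
        for label, (s, e) in spans:
            if s < 1 or e > n:
                raise AnnotationError(
                    f"{self.protein_id}: {label} span ({s}, {e}) outside "
                    f"sequence bounds [1, {n}]"
                )
        for p in self.ptms:
            if p.position is not None and p.position > n:
                raise AnnotationError(
                    f"{self.protein_id}: PTM position {p.position} outside "
                    f"sequence bounds [1, {n}]"
                )


@dataclass
class BackgroundSet:
    """A background proteome for enrichment testing.

    ``label`` is either ``proteome`` (whole proteome, no TMD information)
    or ``membrane_proteome`` (every entry carries >= 1 TMD span).
    """

    label: str
    records: list[ProteinRecord]
    tmds: dict[str, list[TMDSpan]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("proteome", "membrane_proteome"):
            raise AnnotationError(f"unknown background label {self.label!r}")
        if self.label == "membrane_proteome":
            missing = [r.id for r in self.records if not self.tmds.get(r.id)]
            if missing:
                raise AnnotationError(
                    f"membrane_proteome entries lack TMD spans: {missing[:5]}"
                )

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file.

    Record ids are taken from the header up to the first whitespace and
    sequences are upper-cased.  Illegal residues raise
    :class:`AnnotationError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, name=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

_COLUMNS = [
    "protein_id", "name", "tffd_start", "tffd_end", "tmd_index",
    "tmd_start", "tmd_end", "tmd_score", "topology", "nls",
    "localizations", "ptm_kind", "ptm_position", "helix_motif",
    "kr_tmd", "kr_flank", "n_alt_transcripts",
]

_KR_RE = re.compile(r"([KR])\((\d+)\)")


def _parse_kr(cell: str) -> tuple[Optional[tuple[int, int]], bool]:
    """Parse a "K(3) R(1)" style cell into (K count, R count) + significance flag."""
    cell = cell.strip()
    if not cell:
        return None, False
    significant = cell.endswith("*")
    cell = cell.rstrip("*").strip()
    if cell == "0":
        return (0, 0), significant
    counts = {"K": 0, "R": 0}
    matched = False
    for aa, n in _KR_RE.findall(cell):
        counts[aa] += int(n)
        matched = True
    if not matched:
        raise AnnotationError(f"cannot parse K/R count cell {cell!r}")
    return (counts["K"], counts["R"]), significant


def _format_kr(kr: Optional[tuple[int, int]], significant: bool) -> str:
    if kr is None:
        return ""
    k, r = kr
    if k == 0 and r == 0:
        body = "0"
    else:
        parts = []
        if k:
            parts.append(f"K({k})")
        if r:
            parts.append(f"R({r})")
        body = " ".join(parts)
    return body + ("*" if significant else "")


def _parse_ptms(cell: str, position_cell: str) -> list[PTMRecord]:
    """Parse a PTM cell.

    Tokens are semicolon-separated.  Count notation ``ph(3)*`` means three
    phosphorylation sites at unknown positions, the ``*`` marking that at
    least one falls between the TFFD and the TMD.  Positioned notation
    ``ph@150`` records a single site at residue 150.  A bare abbreviation
    takes its position from the ``ptm_position`` column when present.
    """
    cell = cell.strip()
    if not cell:
        return []
    ptms: list[PTMRecord] = []
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        between = token.endswith("*")
        token = token.rstrip("*")
        m = re.fullmatch(r"([a-z]{2})(?:\((\d+)\)|@(\d+))?", token)
        if not m or m.group(1) not in PTM_KINDS:
            raise AnnotationError(f"cannot parse PTM token {token!r}")
        abbrev, count, pos = m.group(1), m.group(2), m.group(3)
        kind = PTM_KINDS[abbrev]
        if pos is not None:
            ptms.append(PTMRecord(kind=kind, position=int(pos),
                                  between_domains=between))
        elif count is not None:
            for i in range(int(count)):
                ptms.append(PTMRecord(kind=kind,
                                      between_domains=between and i == 0))
        else:
            p = int(position_cell) if position_cell.strip() else None
            ptms.append(PTMRecord(kind=kind, position=p,
                                  between_domains=between))
    return ptms


def _format_ptms(ptms: Sequence[PTMRecord]) -> str:
    counted: dict[str, tuple[int, bool]] = {}
    tokens: list[str] = []
    for p in ptms:
        ab = _PTM_ABBREV[p.kind]
        if p.position is not None:
            tokens.append(f"{ab}@{p.position}" + ("*" if p.between_domains else ""))
        else:
            n, between = counted.get(ab, (0, False))
            counted[ab] = (n + 1, between or p.between_domains)
    tokens.extend(
        f"{ab}({n})" + ("*" if between else "")
        for ab, (n, between) in sorted(counted.items())
    )
    return ";".join(tokens)


def read_annotations(path: str | Path,
                     sequences: Optional[Sequence[ProteinRecord]] = None,
                     ) -> list[DomainAnnotation]:
    """Read a per-protein annotation TSV.

    Multiple TMD rows for the same protein id are merged into a single
    :class:`DomainAnnotation` with an ordered ``tmds`` list (ordered by
    ``tmd_index``).  If ``sequences`` is given, spans are validated
    against sequence bounds.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(_COLUMNS) - set(header)
        if missing:
            raise AnnotationError(f"annotation TSV missing columns: {sorted(missing)}")
        idx = {c: header.index(c) for c in header}
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            cells += [""] * (len(header) - len(cells))
            rows.append((lineno, {c: cells[i] for c, i in idx.items()}))

    by_id: dict[str, list[dict]] = {}
    order: list[str] = []
    for lineno, row in rows:
        pid = row["protein_id"].strip()
        if not pid:
            raise AnnotationError(f"line {lineno}: empty protein_id")
        if pid not in by_id:
            by_id[pid] = []
            order.append(pid)
        by_id[pid].append(row)

    annotations = []
    for pid in order:
        prows = sorted(by_id[pid], key=lambda r: int(r["tmd_index"] or 1))
        first = prows[0]
        tmds = []
        helix_motifs = []
        for row in prows:
            score = float(row["tmd_score"]) if row["tmd_score"].strip() else None
            topo = row["topology"].strip() or "NA"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tmds.append(TMDSpan(
                    start=int(row["tmd_start"]), end=int(row["tmd_end"]),
                    score=score, topology=topo,
                ))
            # aligned with tmds: one entry per TMD row, "" when blank
            helix_motifs.append(row["helix_motif"].strip().strip("[]"))
        locs = frozenset(
            tok.strip().lower()
            for tok in first["localizations"].split(";") if tok.strip()
        )
        unknown = locs - LOCALIZATION_LABELS
        if unknown:
            raise AnnotationError(f"{pid}: unknown localization labels {sorted(unknown)}")
        nls_cell = first["nls"].strip().lower()
        nls = None if nls_cell == "" else nls_cell in ("1", "true", "yes", "y")
        # kr_tmd cells may be given per TMD row; keep the element-wise
        # maximum so the protein-level value reflects "any listed TMD"
        kr_tmd: Optional[tuple[int, int]] = None
        for row in prows:
            kr_row, _ = _parse_kr(row["kr_tmd"])
            if kr_row is not None:
                kr_tmd = kr_row if kr_tmd is None else (
                    max(kr_tmd[0], kr_row[0]), max(kr_tmd[1], kr_row[1]))
        kr_flank, kr_sig = _parse_kr(first["kr_flank"])
        alt = int(first["n_alt_transcripts"]) if first["n_alt_transcripts"].strip() else 0
        ann = DomainAnnotation(
            protein_id=pid,
            name=first["name"].strip() or pid,
            tffd=(int(first["tffd_start"]), int(first["tffd_end"])),
            tmds=tmds,
            nls_present=nls,
            localizations=locs,
            ptms=_parse_ptms(first["ptm_kind"], first["ptm_position"]),
            helix_motifs=helix_motifs,
            kr_tmd=kr_tmd,
            kr_flank=kr_flank,
            kr_flank_significant=kr_sig,
            n_alt_transcripts=alt,
        )
        annotations.append(ann)

    if sequences is not None:
        by_seq = {r.id: r for r in sequences}
        for ann in annotations:
            if ann.protein_id in by_seq:
                ann.validate_against(by_seq[ann.protein_id])
    return annotations


def write_annotations(annotations: Iterable[DomainAnnotation],
                      path: str | Path) -> None:
    """Write annotations in the TSV schema read by :func:`read_annotations`."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for ann in annotations:
            ptm_cell = _format_ptms(ann.ptms)
            helix = list(ann.helix_motifs) + [""] * (len(ann.tmds) - len(ann.helix_motifs))
            for i, tmd in enumerate(ann.tmds, start=1):
                row = [
                    ann.protein_id, ann.name,
                    str(ann.tffd[0]), str(ann.tffd[1]),
                    str(i), str(tmd.start), str(tmd.end),
                    "" if tmd.score is None else f"{tmd.score:g}",
                    "" if tmd.topology == "NA" else tmd.topology,
                    "" if ann.nls_present is None else ("1" if ann.nls_present else "0"),
                    ";".join(sorted(ann.localizations)),
                    ptm_cell, "",
                    f"[{helix[i - 1]}]" if helix[i - 1] else "",
                    _format_kr(ann.kr_tmd, False) if i == 1 else "",
                    _format_kr(ann.kr_flank, ann.kr_flank_significant) if i == 1 else "",
                    str(ann.n_alt_transcripts) if ann.n_alt_transcripts else "",
                ]
                fh.write("\t".join(row) + "\n")


def load_table1_fixture() -> list[DomainAnnotation]:
    """Load the packaged 52-protein Arabidopsis MB-TF annotation table.

    The table records, per protein, the TFFD and TMD coordinates,
    mean-hydrophobicity TMD score, type-I/II topology call, subcellular
    localisations, PTM counts, helix-breaking motifs found in the TMD,
    externally annotated K/R counts (TMD and 20-residue TFFD-side flank,
    with significance flags), and the number of TMD-lacking alternative
    transcripts.  Protein sequences are not packaged; fixture-level
    statistics are computed from the annotation columns alone.
    """
    ref = importlib.resources.files("ripscan.data").joinpath("atmbtf_table1.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_annotations(path)
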