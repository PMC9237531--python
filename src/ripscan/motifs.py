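"""Degenerate protease/helix motif compilation and TMD-window scanning.

Motifs are written in the degenerate notation used throughout the
intramembrane-protease literature: literal residues, ``x`` for any residue,
``[SET]`` for an allowed set and ``[^SET]`` for the complement of a set
(any standard residue except those listed).  Examples are the site-1
protease (S1P) consensus ``Rx[LIT][KL]``, the rhomboid recognition site
``LxLSIxGA`` found in the NTL7 TMD, and short helix-destabilising motifs
such as ``NP`` and ``GxxN``.

Matching semantics:

* ``x`` matches the unknown residue ``X``; literal, set and complement
  tokens never match ``X`` (conservative calling).
* Reverse-orientation scanning reverses the token order (proteins have no
  complement strand); it is used for helix-destabilising motifs whose
  effect is direction-agnostic.
* All (possibly overlapping) matches are reported; presence/absence
  collapsing happens only in :func:`protein_has_motif`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .annotations import AMINO_ACIDS, DomainAnnotation, ProteinRecord

__all__ = [
    "MotifPattern",
    "MotifHit",
    "MotifCatalog",
    "MotifParseError",
    "compile_pattern",
    "scan_window",
    "protein_has_motif",
    "default_catalog",
    "load_catalog",
]

_STANDARD = frozenset(AMINO_ACIDS)
_ANY = frozenset(AMINO_ACIDS + "X")


class MotifParseError(ValueError):
    """Raised when a motif notation string cannot be compiled."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif.

    ``tokens`` is the ordered tuple of per-position residue sets; a match
    at position i requires ``sequence[i + j] in tokens[j]`` for every j.
    ``cleavage_offsets`` (optional) are inter-residue positions within the
    match recorded as metadata, counted as the number of tokens before the
    scissile bond.
    """

    name: str
    notation: str
    tokens: tuple[frozenset[str], ...]
    category: str = "protease_recognition"
    source: str = ""
    orientations: tuple[str, ...] = ("forward",)
    cleavage_offsets: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if len(self.tokens) < 2:
            raise MotifParseError(f"{self.name}: motif needs >= 2 positions")
        if self.category not in ("protease_recognition", "helix_destabilizing"):
            raise MotifParseError(f"{self.name}: unknown category {self.category!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def match_probability(self) -> float:
        """Per-position match probability under i.i.d. uniform residues."""
        p = 1.0
        for tok in self.tokens:
            p *= len(tok - {"X"}) / 20.0
        return p


@dataclass(frozen=True)
class MotifHit:
    """A located motif match (1-based inclusive span)."""

    protein_id: str
    motif_name: str
    start: int
    end: int
    matched_peptide: str
    orientation: str = "forward"
    window_label: str = "full"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def compile_pattern(notation: str, name: Optional[str] = None,
                    category: str = "protease_recognition",
                    source: str = "",
                    orientations: Sequence[str] = ("forward",),
                    cleavage_offsets: Optional[Sequence[int]] = None,
                    ) -> MotifPattern:
    """Compile degenerate motif notation into a :class:`MotifPattern`.

    >>> p = compile_pattern("Rx[LIT][KL]")
    >>> [sorted(t - {"X"}) for t in p.tokens][0]
    ['R']
    """
    tokens: list[frozenset[str]] = []
    i = 0
    n = len(notation)
    while i < n:
        c = notation[i]
        if c == "x":
            tokens.append(_ANY)
            i += 1
        elif c == "[":
            j = notation.find("]", i)
            if j < 0:
                raise MotifParseError(
                    f"unbalanced bracket at column {i} in {notation!r}")
            body = notation[i + 1:j]
            complement = body.startswith("^")
            if complement:
                body = body[1:]
            if not body:
                raise MotifParseError(f"empty set at column {i} in {notation!r}")
            bad = set(body) - _STANDARD
            if bad:
                raise MotifParseError(
                    f"illegal residue {sorted(bad)} at column {i} in {notation!r}")
            members = frozenset(body)
            tokens.append(_STANDARD - members if complement else members)
            i = j + 1
        elif c in _STANDARD:
            tokens.append(frozenset(c))
            i += 1
        else:
            raise MotifParseError(
                f"illegal character {c!r} at column {i} in {notation!r}")
    return MotifPattern(
        name=name or notation,
        notation=notation,
        tokens=tuple(tokens),
        category=category,
        source=source,
        orientations=tuple(orientations),
        cleavage_offsets=tuple(cleavage_offsets) if cleavage_offsets else None,
    )


def scan_window(record: ProteinRecord, pattern: MotifPattern,
                window: tuple[int, int], orientation: str = "forward",
                window_label: str = "full") -> list[MotifHit]:
    """Report every match of ``pattern`` lying entirely inside ``window``.

    ``window`` is a 1-based inclusive residue span; ``(s, e)`` with
    ``e < s`` denotes an empty window.  Reverse orientation scans with the
    token order reversed.
    """
    s, e = window
    if e < s:
        return []
    if s < 1 or e > record.length:
        raise ValueError(
            f"window ({s}, {e}) outside sequence bounds [1, {record.length}] "
            f"for {record.id}")
    tokens = pattern.tokens if orientation == "forward" else pattern.tokens[::-1]
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"unknown orientation {orientation!r}")
    m = len(tokens)
    seq = record.sequence
    hits = []
    for start0 in range(s - 1, e - m + 1):  # 0-based candidate starts
        for j, tok in enumerate(tokens):
            if seq[start0 + j] not in tok:
                break
        else:
            hits.append(MotifHit(
                protein_id=record.id,
                motif_name=pattern.name,
                start=start0 + 1,
                end=start0 + m,
                matched_peptide=seq[start0:start0 + m],
                orientation=orientation,
                window_label=window_label,
            ))
    return hits


def protein_has_motif(record: ProteinRecord, annotation: Optional[DomainAnnotation],
                      pattern: MotifPattern, window_spec: str = "full",
                      orientations: Optional[Sequence[str]] = None,
                      k: int = 20, tmd_policy: str | int = "first") -> bool:
    """True iff the motif matches at least once in the selected window(s).

    ``window_spec`` is a window label understood by
    :func:`ripscan.features.resolve_window` ("full", "tmd",
    "tmd_plus_flank", "flank_tffd_side"); TMD-anchored windows need an
    ``annotation``.  All TMDs selected by ``tmd_policy`` are scanned.
    """
    from .features import resolve_window  # local import to avoid a cycle

    if orientations is None:
        orientations = pattern.orientations
    if window_spec == "full":
        windows = [((1, record.length), "full")]
    else:
        if annotation is None:
            raise ValueError("TMD-anchored windows require an annotation")
        policies = (range(len(annotation.tmds)) if tmd_policy == "all"
                    else [tmd_policy])
        windows = [
            (resolve_window(annotation, window_spec, k=k, tmd_policy=p,
                            length=record.length).span, window_spec)
            for p in policies
        ]
    for span, label in windows:
        for orient in orientations:
            if scan_window(record, pattern, span, orient, window_label=label):
                return True
    return False


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

#: Built-in motif definitions: (name, notation, category, source,
#: orientations, cleavage offsets).  Protease-recognition motifs are
#: scanned forward only; helix-destabilising motifs in both orientations
#: because the protease/substrate orientation is generally unknown.
_DEFAULT_DEFS: list[tuple] = [
    ("RRIL", "RRIL", "protease_recognition", "S1P (exact site)",
     ("forward",), None),
    ("S1P-degenerate", "Rx[LIT][KL]", "protease_recognition",
     "S1P (mammalian substrate consensus)", ("forward",), None),
    ("Rho1-NTL7", "LxLSIxGA", "protease_recognition",
     "Drosophila Rho-1 site as found in NTL7",
     ("forward",), (3, 7)),
    ("Rho1-relaxed", "[LF]xLSIxGA", "protease_recognition",
     "Rho-1 site, relaxed first position", ("forward",), (3, 7)),
    ("rhomboid-AarA-type", "[ILMF]xx[GAS][AHS][IMLF]", "protease_recognition",
     "bacterial/fly rhomboid substrates (TatA, LacYTM2, Gurken/Spitz, PINK1)",
     ("forward",), None),
    ("rhomboid-compact", "[ILMF]x[GAS][AHS][IMLF]", "protease_recognition",
     "bacterial/fly rhomboid substrates, compact spacing", ("forward",), None),
    ("pan-rhomboid", "[^WP][IMYFWLV][^WPD][^WF][AGCS][^P][FIMVACLTW]",
     "protease_recognition", "minimal consensus of animal+bacterial rhomboids",
     ("forward",), None),
    ("NP", "NP", "helix_destabilizing", "S1P-dependent RIP substrates",
     ("forward", "reverse"), None),
    ("NxxP", "NxxP", "helix_destabilizing", "S1P-dependent RIP substrates",
     ("forward", "reverse"), None),
    ("PxxP", "PxxP", "helix_destabilizing", "S1P-dependent RIP substrates",
     ("forward", "reverse"), None),
    ("GxxN", "GxxN", "helix_destabilizing", "S1P-dependent RIP substrates",
     ("forward", "reverse"), None),
    ("PxxN", "PxxN", "helix_destabilizing", "helix-breaker variant",
     ("forward", "reverse"), None),
    ("PN", "PN", "helix_destabilizing", "helix-breaker variant",
     ("forward", "reverse"), None),
    ("GA", "GA", "helix_destabilizing", "animal/bacterial rhomboid cleavage",
     ("forward", "reverse"), None),
]


@dataclass
class MotifCatalog:
    """A named collection of compiled motif patterns."""

    patterns: dict[str, MotifPattern] = field(default_factory=dict)

    def __getitem__(self, name: str) -> MotifPattern:
        return self.patterns[name]

    def __iter__(self):
        return iter(self.patterns.values())

    def __len__(self) -> int:
        return len(self.patterns)

    def by_category(self, category: str) -> list[MotifPattern]:
        return [p for p in self if p.category == category]

    @property
    def protease_patterns(self) -> list[MotifPattern]:
        return self.by_category("protease_recognition")

    @property
    def helix_patterns(self) -> list[MotifPattern]:
        return self.by_category("helix_destabilizing")


def default_catalog() -> MotifCatalog:
    """The built-in catalog of protease-recognition and helix motifs."""
    cat = MotifCatalog()
    for name, notation, category, source, orients, offsets in _DEFAULT_DEFS:
        cat.patterns[name] = compile_pattern(
            notation, name=name, category=category, source=source,
            orientations=orients, cleavage_offsets=offsets)
    return cat


def load_catalog(path: str | Path) -> MotifCatalog:
    """Load a motif catalog from a YAML config.

    Each entry: ``name``, ``notation``, ``category``, optional ``source``,
    ``orientations`` (list) and ``cleavage_offsets``.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    cat = MotifCatalog()
    for entry in entries:
        cat.patterns[entry["name"]] = compile_pattern(
            entry["notation"],
            name=entry["name"],
            category=entry.get("category", "protease_recognition"),
            source=entry.get("source", ""),
            orientations=tuple(entry.get("orientations", ["forward"])),
            cleavage_offsets=entry.get("cleavage_offsets"),
        )
    return cat


def dump_catalog(catalog: MotifCatalog, path: str | Path) -> None:
    entries = []
    for p in catalog:
        entry = {
            "name": p.name,
            "notation": p.notation,
            "category": p.category,
            "source": p.source,
            "orientations": list(p.orientations),
        }
        if p.cleavage_offsets:
            entry["cleavage_offsets"] = list(p.cleavage_offsets)
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
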