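"""Synthetic MB-TF cohorts, background proteomes and regulatory networks.

Every pipeline stage is testable without downloads: this module emits
(i) cohorts of i.i.d.-residue proteins with planted hydrophobic TMDs,
TFFD spans placed N-terminal, C-terminal or overlapping the TMD, assigned
type-I/II topologies, motifs written into chosen windows at chosen rates
and controlled K/R composition in TMD flanks; (ii) background sets (whole
proteome and membrane proteome with TMD spans) with controlled feature
base-rates; and (iii) TF->target networks with block-structured GO-BP
labels.  Each generator records complete ground truth and is
byte-reproducible for a fixed seed.

Default condition sizes mirror the Arabidopsis MB-TF study design: a
57-protein analysis cohort whose TMD-position classes split roughly
60/24/16% into C-terminal, N-terminal and TFFD-overlapping, with
type-II/type-I/no-call topology fractions per class as observed there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .annotations import (
    AMINO_ACIDS,
    BackgroundSet,
    DomainAnnotation,
    ProteinRecord,
    TMDSpan,
)
from .motifs import MotifPattern, compile_pattern
from .network import RegulatoryNetwork

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "SpecError",
    "generate_cohort",
    "generate_background",
    "generate_network",
]

#: Residues favoured inside planted transmembrane helices.
HYDROPHOBIC = "AILMFVWC"


class SpecError(ValueError):
    """Raised when a synthetic specification is infeasible."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    ``motif_plan`` maps motif notation -> (planting rate in [0, 1],
    window label), where the window label is one of ``tmd``,
    ``tmd_plus_flank``, ``flank_tffd_side``, ``luminal_tail`` (the
    non-TFFD side of the TMD, where S1P-type cleavage happens for
    luminal-tail substrates) or ``full``.  ``charge_plan`` optionally
    plants ``n_kr`` positively charged residues into the ``k``-residue
    TFFD-side flank.
    """

    n_proteins: int = 57
    length_range: tuple[int, int] = (300, 800)
    residue_freqs: Optional[dict[str, float]] = None  # uniform when None
    tmd_length_range: tuple[int, int] = (18, 25)
    tmd_hydrophobic_bias: float = 0.9
    position_class_probs: dict[str, float] = field(
        default_factory=lambda: {"C": 0.603, "N": 0.238, "overlap": 0.159})
    topology_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "C": {"II": 0.595, "I": 0.215, "NA": 0.19},
            "N": {"I": 0.266, "II": 0.266, "NA": 0.468},
            "overlap": {"NA": 1.0},
        })
    motif_plan: dict[str, tuple[float, str]] = field(default_factory=dict)
    charge_plan: Optional[tuple[int, int]] = None  # (n_kr, flank size k)
    flank_k: int = 20
    # backgrounds
    n_proteome: int = 2000
    n_membrane: int = 1000
    background_motif_rates: dict[str, float] = field(default_factory=dict)
    background_length_range: tuple[int, int] = (150, 600)
    # network
    n_tf_blocks: int = 4
    tfs_per_block: int = 5
    genes_per_block: int = 50
    targets_per_tf: int = 20
    wiring_rate: float = 0.8
    noise_term_rate: float = 0.05
    n_noise_terms: int = 10
    max_plant_retries: int = 100


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    proteins: dict[str, dict] = field(default_factory=dict)
    blocks: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"proteins": self.proteins, "blocks": self.blocks},
                      fh, indent=1, sort_keys=True)


def _residue_sampler(spec: SyntheticSpec):
    if spec.residue_freqs is None:
        letters = np.array(list(AMINO_ACIDS))
        probs = None
    else:
        letters = np.array(list(spec.residue_freqs))
        probs = np.array([spec.residue_freqs[l] for l in letters], dtype=float)
        probs = probs / probs.sum()

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(letters, size=n, p=probs)

    return draw


def _draw_tmd(rng: np.random.Generator, length: int,
              bias: float) -> np.ndarray:
    hydro = np.array(list(HYDROPHOBIC))
    allaa = np.array(list(AMINO_ACIDS))
    mask = rng.random(length) < bias
    out = rng.choice(allaa, size=length)
    out[mask] = rng.choice(hydro, size=int(mask.sum()))
    return out


def _choose(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), p=p)]


def _instantiate(rng: np.random.Generator, pattern: MotifPattern) -> str:
    """A concrete peptide matching the pattern (uniform within each token)."""
    out = []
    for tok in pattern.tokens:
        choices = sorted(tok - {"X"})
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _plan_window(window_label: str, tffd: tuple[int, int], tmd: TMDSpan,
                 length: int, k: int) -> tuple[int, int]:
    """Resolve a planting window label to a 1-based inclusive span."""
    if window_label == "full":
        return 1, length
    if window_label == "tmd":
        return tmd.start, tmd.end
    if window_label == "tmd_plus_flank":
        return max(1, tmd.start - k), min(length, tmd.end + k)
    tffd_left = tffd[1] < tmd.start
    if window_label == "flank_tffd_side":
        if tffd_left:
            return max(1, tmd.start - k), tmd.start - 1
        return tmd.end + 1, min(length, tmd.end + k)
    if window_label == "luminal_tail":
        # the side opposite the TFFD
        if tffd_left:
            return tmd.end + 1, length
        return 1, tmd.start - 1
    raise SpecError(f"unknown planting window {window_label!r}")


def _plant_motifs(rng: np.random.Generator, seq: np.ndarray,
                  plan: dict[str, tuple[float, str]],
                  tffd: tuple[int, int], tmd: TMDSpan,
                  k: int, max_retries: int,
                  reserved: list[tuple[int, int]],
                  ) -> list[dict]:
    """Write planned motifs into ``seq`` in place; returns truth entries."""
    planted = []
    length = len(seq)
    for notation, (rate, window_label) in plan.items():
        pattern = compile_pattern(notation)
        ws, we = _plan_window(window_label, tffd, tmd, length, k)
        m = len(pattern)
        if we - ws + 1 < m:
            raise SpecError(
                f"motif {notation!r} (length {m}) does not fit window "
                f"{window_label!r} = ({ws}, {we})")
        if rng.random() >= rate:
            continue
        placed = False
        for _ in range(max_retries):
            start = int(rng.integers(ws, we - m + 2))  # 1-based
            span = (start, start + m - 1)
            if any(not (span[1] < s or span[0] > e) for s, e in reserved):
                continue
            peptide = _instantiate(rng, pattern)
            seq[start - 1:start - 1 + m] = list(peptide)
            reserved.append(span)
            planted.append({
                "motif": pattern.name, "notation": notation,
                "span": list(span), "window": window_label,
                "peptide": peptide,
            })
            placed = True
            break
        if not placed:
            raise SpecError(
                f"could not place motif {notation!r} in window "
                f"{window_label!r} after {max_retries} retries")
    return planted


def generate_cohort(spec: SyntheticSpec, seed: int = 0,
                    ) -> tuple[list[ProteinRecord], list[DomainAnnotation],
                               SyntheticTruth]:
    """Generate a synthetic MB-TF cohort with planted features.

    Motif and charge planting apply to non-overlap proteins only (the
    pipeline excludes overlap-class proteins from feature scans, so
    planting there would create unrecoverable truth).
    """
    rng = np.random.default_rng(seed)
    draw = _residue_sampler(spec)
    lo, hi = spec.length_range
    tlo, thi = spec.tmd_length_range
    records, annotations = [], []
    truth = SyntheticTruth()
    for i in range(spec.n_proteins):
        pid = f"SYN{i + 1:04d}"
        L = int(rng.integers(lo, hi + 1))
        seq = draw(rng, L)
        t = int(rng.integers(tlo, thi + 1))
        pclass = _choose(rng, spec.position_class_probs)
        k = spec.flank_k
        tffd_len = int(rng.integers(60, 131))
        if pclass == "C":
            # TFFD near the N-terminus, TMD in the C-terminal part
            tffd_start = int(rng.integers(2, 31))
            tffd = (tffd_start, tffd_start + tffd_len - 1)
            tmd_lo = tffd[1] + k + 25
            tmd_hi = L - t - 5
            if tmd_hi < tmd_lo:
                tmd_lo, tmd_hi = min(tffd[1] + 2, L - t), L - t
            tmd_start = int(rng.integers(tmd_lo, tmd_hi + 1))
        elif pclass == "N":
            tmd_start = int(rng.integers(6, 31))
            tffd_lo = tmd_start + t + k + 25
            tffd_start = int(rng.integers(tffd_lo, max(tffd_lo + 1,
                                                       L - tffd_len - 2)))
            tffd = (tffd_start, min(L, tffd_start + tffd_len - 1))
        else:  # overlap: TMD inside the TFFD
            tffd_start = int(rng.integers(10, max(11, L - tffd_len - 10)))
            tffd = (tffd_start, tffd_start + tffd_len - 1)
            tmd_start = int(rng.integers(tffd[0], tffd[1] - t + 2))
        tmd_span = (tmd_start, tmd_start + t - 1)
        seq[tmd_span[0] - 1:tmd_span[1]] = _draw_tmd(rng, t,
                                                     spec.tmd_hydrophobic_bias)
        topology = _choose(rng, spec.topology_probs[pclass])
        tmd = TMDSpan(start=tmd_span[0], end=tmd_span[1],
                      score=None, topology=topology)

        planted: list[dict] = []
        charge_truth = None
        if pclass != "overlap":
            reserved = []
            planted = _plant_motifs(rng, seq, spec.motif_plan, tffd, tmd,
                                    k, spec.max_plant_retries, reserved)
            if spec.charge_plan is not None:
                n_kr, ck = spec.charge_plan
                fs, fe = _plan_window("flank_tffd_side", tffd, tmd, L, ck)
                avail = [p for p in range(fs, fe + 1)
                         if all(not (s <= p <= e) for s, e in reserved)]
                if len(avail) < n_kr:
                    raise SpecError(
                        f"cannot plant {n_kr} K/R into flank of length "
                        f"{fe - fs + 1}")
                pos = rng.choice(len(avail), size=n_kr, replace=False)
                chosen = sorted(avail[j] for j in pos)
                # strip background K/R over the whole TFFD-side flank so
                # the planted count is the exact charge composition of
                # every nesting flank window (verifiable truth)
                ws, we = _plan_window("flank_tffd_side", tffd, tmd, L,
                                      max(ck, spec.flank_k))
                for p in range(ws, we + 1):
                    if seq[p - 1] in ("K", "R") and p not in chosen:
                        seq[p - 1] = "A"
                for p in chosen:
                    seq[p - 1] = "K" if rng.random() < 0.5 else "R"
                charge_truth = {"n_kr": n_kr, "window_k": ck,
                                "positions": chosen}

        side = {"C": {"II": "cytosolic", "I": "luminal"},
                "N": {"I": "cytosolic", "II": "luminal"}}.get(
                    pclass, {}).get(topology, "NA")
        record = ProteinRecord(id=pid, sequence="".join(seq))
        ann = DomainAnnotation(protein_id=pid, tffd=tffd, tmds=[tmd])
        records.append(record)
        annotations.append(ann)
        truth.proteins[pid] = {
            "length": L,
            "position_class": pclass,
            "topology": topology,
            "tffd_side": side,
            "tffd": list(tffd),
            "tmd": list(tmd_span),
            "planted_motifs": planted,
            "planted_charge": charge_truth,
        }
    return records, annotations, truth


def generate_background(spec: SyntheticSpec, seed: int = 0,
                        ) -> tuple[BackgroundSet, BackgroundSet]:
    """Generate the (proteome, membrane_proteome) background pair.

    The proteome carries no TMD annotation; every membrane-proteome entry
    has one planted TMD.  ``background_motif_rates`` plant motifs at
    controlled base-rates: into the full sequence for the proteome and
    into the TMD +/- flank region for the membrane set.
    """
    rng = np.random.default_rng(seed)
    draw = _residue_sampler(spec)
    lo, hi = spec.background_length_range
    tlo, thi = spec.tmd_length_range

    def make_set(n: int, with_tmd: bool, prefix: str
                 ) -> tuple[list[ProteinRecord], dict[str, list[TMDSpan]]]:
        records, tmds = [], {}
        for i in range(n):
            pid = f"{prefix}{i + 1:05d}"
            L = int(rng.integers(lo, hi + 1))
            seq = draw(rng, L)
            tmd = None
            if with_tmd:
                t = int(rng.integers(tlo, thi + 1))
                start = int(rng.integers(spec.flank_k + 2,
                                         max(spec.flank_k + 3, L - t - spec.flank_k)))
                seq[start - 1:start - 1 + t] = _draw_tmd(
                    rng, t, spec.tmd_hydrophobic_bias)
                tmd = TMDSpan(start=start, end=start + t - 1)
                tmds[pid] = [tmd]
            for notation, rate in spec.background_motif_rates.items():
                if rng.random() >= rate:
                    continue
                pattern = compile_pattern(notation)
                m = len(pattern)
                if tmd is not None:
                    ws = max(1, tmd.start - spec.flank_k)
                    we = min(L, tmd.end + spec.flank_k)
                else:
                    ws, we = 1, L
                if we - ws + 1 < m:
                    raise SpecError(f"motif {notation!r} does not fit background window")
                start0 = int(rng.integers(ws, we - m + 2))
                seq[start0 - 1:start0 - 1 + m] = list(_instantiate(rng, pattern))
            records.append(ProteinRecord(id=pid, sequence="".join(seq)))
        return records, tmds

    prot_records, _ = make_set(spec.n_proteome, False, "BGP")
    mem_records, mem_tmds = make_set(spec.n_membrane, True, "BGM")
    proteome = BackgroundSet(label="proteome", records=prot_records)
    membrane = BackgroundSet(label="membrane_proteome", records=mem_records,
                             tmds=mem_tmds)
    return proteome, membrane


def generate_network(spec: SyntheticSpec, seed: int = 0,
                     ) -> tuple[RegulatoryNetwork, SyntheticTruth]:
    """Block-structured TF->target network with GO-BP labels.

    Genes are split into ``n_tf_blocks`` blocks; block b's genes all
    carry the block term ``GO:BLOCK{b}``.  Each TF draws each of its
    targets from its own block with probability ``wiring_rate`` and
    uniformly from the whole universe otherwise.  Noise terms annotate
    random genes at ``noise_term_rate``.
    """
    rng = np.random.default_rng(seed)
    n_blocks = spec.n_tf_blocks
    genes = [f"G{i + 1:05d}" for i in range(n_blocks * spec.genes_per_block)]
    universe = frozenset(genes)
    block_of_gene = {g: i // spec.genes_per_block for i, g in enumerate(genes)}
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        annotations[g].add(f"GO:BLOCK{block_of_gene[g]}")
    for j in range(spec.n_noise_terms):
        term = f"GO:NOISE{j}"
        for g in genes:
            if rng.random() < spec.noise_term_rate:
                annotations[g].add(term)

    truth = SyntheticTruth()
    edges: dict[str, frozenset[str]] = {}
    gene_arr = np.array(genes)
    for b in range(n_blocks):
        block_genes = gene_arr[b * spec.genes_per_block:
                               (b + 1) * spec.genes_per_block]
        for j in range(spec.tfs_per_block):
            tf = f"TF{b}_{j}"
            truth.blocks[tf] = b
            targets: set[str] = set()
            while len(targets) < spec.targets_per_tf:
                if rng.random() < spec.wiring_rate:
                    targets.add(str(block_genes[rng.integers(0, len(block_genes))]))
                else:
                    targets.add(str(gene_arr[rng.integers(0, len(gene_arr))]))
            edges[tf] = frozenset(targets)
    network = RegulatoryNetwork(
        edges=edges,
        annotations={g: frozenset(ts) for g, ts in annotations.items()},
        universe=universe,
    )
    return network, truth
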