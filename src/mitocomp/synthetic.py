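"""Seeded generator of annotated circular mitogenomes with ground truth.

The generator emits genomes with the statistical structure the analysis
modules assume: the 37-gene ancestral insect order, configurable A+T
content and strand skews, protein-coding genes with ATN starts, TAA/TAG or
incomplete-T stops and no internal stops under the invertebrate
mitochondrial code, junction overlaps/spacers realized exactly on a single
shared sequence, and a long A+T-rich control region with tandem repeats.

Composition targeting is analytic: plus-strand base probabilities are
solved from (A+T fraction, AT-skew, GC-skew) as

    p_A = at*(1+s_AT)/2     p_T = at*(1-s_AT)/2
    p_G = gc*(1+s_GC)/2     p_C = gc*(1-s_GC)/2

with region-specific A+T levels (control region, per-codon-position PCG
targets) balanced against the rest of the genome so the whole-genome
mixture still hits the global targets. PCG body codons are drawn from the
exact conditional distribution given "not a stop codon", with per-position
marginals calibrated by iterative proportional fitting, so stop exclusion
does not bias realized composition. Ground truth records realized counts
from the emitted sequence, not the targets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .architecture import ANCESTRAL_GENE_ORDER, GeneOrder
from .composition import BaseCounts
from .genetic_code import STOP_CODONS
from .mito_io import (
    CR_NAME,
    GeneFeature,
    MitoGenome,
    PCG_NAMES,
    RRNA_NAMES,
    TRNA_NAMES,
    extract_feature_sequence,
    gene_class_for_name,
)
from .trna import CloverleafStructure

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class GenerationError(ValueError):
    """Raised when a spec is infeasible before any sequence is drawn."""


# ---------------------------------------------------------------------------
# defaults: a daozhenensis-like genome (see presets module for the other
# published-table parameterizations)

DEFAULT_PCG_LENGTHS: Dict[str, int] = {
    "nad2": 975, "cox1": 1539, "cox2": 679, "atp8": 153, "atp6": 654,
    "cox3": 780, "nad3": 354, "nad5": 1674, "nad4": 1308, "nad4l": 276,
    "nad6": 483, "cob": 1137, "nad1": 933,
}
DEFAULT_START_CODONS: Dict[str, str] = {
    "nad2": "ATT", "cox1": "ATG", "cox2": "ATA", "atp8": "ATA",
    "atp6": "ATG", "cox3": "ATG", "nad3": "ATT", "nad5": "ATT",
    "nad4": "ATG", "nad4l": "ATT", "nad6": "ATT", "cob": "ATG",
    "nad1": "ATA",
}
#: stop spec: "TAA"/"TAG" complete, or "T"/"TA" incomplete tails
DEFAULT_STOP_CODONS: Dict[str, str] = {
    "nad2": "TAG", "cox1": "TAA", "cox2": "T", "atp8": "TAA",
    "atp6": "TAA", "cox3": "TAA", "nad3": "TAG", "nad5": "TAG",
    "nad4": "TAA", "nad4l": "TAA", "nad6": "TAA", "cob": "TAA",
    "nad1": "TAA",
}
DEFAULT_TRNA_LENGTHS: Dict[str, int] = {
    "trnI": 66, "trnQ": 68, "trnM": 68, "trnW": 66, "trnC": 62,
    "trnY": 65, "trnL2": 66, "trnK": 70, "trnD": 66, "trnG": 64,
    "trnA": 64, "trnR": 62, "trnN": 65, "trnS1": 61, "trnE": 64,
    "trnF": 64, "trnH": 64, "trnT": 64, "trnP": 65, "trnS2": 67,
    "trnL1": 64, "trnV": 76,
}
DEFAULT_GENE_LENGTHS: Dict[str, int] = {
    **DEFAULT_PCG_LENGTHS, **DEFAULT_TRNA_LENGTHS,
    "rrnL": 1204, "rrnS": 745, CR_NAME: 2035,
}
DEFAULT_JUNCTION_GAPS: Dict[Tuple[str, str], int] = {
    ("trnI", "trnQ"): -3, ("nad2", "trnW"): -8, ("trnD", "atp8"): -7,
    ("trnG", "nad3"): -2, ("trnA", "trnR"): -1, ("trnR", "trnN"): -1,
    ("trnN", "trnS1"): -4, ("nad5", "trnH"): -1, ("trnH", "nad4"): -7,
    ("trnP", "nad6"): -1, ("cob", "trnS2"): -1,
    ("trnQ", "trnM"): 2, ("trnC", "trnY"): 38, ("trnY", "cox1"): 2,
    ("cox2", "trnK"): 1, ("trnK", "trnD"): 1, ("trnE", "trnF"): 1,
    ("trnS2", "nad1"): 12,
}
#: anticodons (DNA alphabet) for the 22 tRNAs
TRNA_ANTICODONS: Dict[str, str] = {
    "trnI": "GAT", "trnQ": "TTG", "trnM": "CAT", "trnW": "TCA",
    "trnC": "GCA", "trnY": "GTA", "trnL2": "TAA", "trnK": "CTT",
    "trnD": "GTC", "trnG": "TCC", "trnA": "TGC", "trnR": "TCG",
    "trnN": "GTT", "trnS1": "GCT", "trnE": "TTC", "trnF": "GAA",
    "trnH": "GTG", "trnT": "TGT", "trnP": "TGG", "trnS2": "TGA",
    "trnL1": "TAG", "trnV": "TAC",
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome.

    Defaults emulate the MZ274046-like genome: published per-gene lengths,
    ancestral order, the published junction overlaps (e.g. trnD-atp8 = -7),
    whole-genome A+T 0.762 with AT-skew 0.091 / GC-skew -0.144, control
    region A+T 0.825, and codon-position A+T targets (0.781, 0.711, 0.729).
    """

    seed: int = 0
    gene_lengths: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    gene_order: GeneOrder = ANCESTRAL_GENE_ORDER
    junction_gaps: Dict[Tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_JUNCTION_GAPS))
    start_codons: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_START_CODONS))
    stop_codons: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STOP_CODONS))
    at_fraction: float = 0.762
    at_skew_target: float = 0.091
    gc_skew_target: float = -0.144
    cr_at_fraction: float = 0.825
    cr_at_skew: float = 0.011
    cr_gc_skew: float = -0.103
    pcg_position_at: Tuple[float, float, float] = (0.781, 0.711, 0.729)
    cr_repeat_unit_bp: int = 50
    cr_repeat_copies: int = 4
    cr_wraps_origin: bool = False
    record_id: str = "SYNTH0001"
    organism: str = "synthetic leafhopper"


@dataclass
class GroundTruth:
    """Realized (not target) bookkeeping for one generated genome."""

    genome_length: int
    gene_order: GeneOrder
    strands: Dict[str, str]
    gene_lengths: Dict[str, int]
    junction_gaps: Dict[Tuple[str, str], int]
    start_codons: Dict[str, str]
    stop_codons: Dict[str, str]
    codon_counts: Counter
    total_nonstop_codons: int
    region_counts: Dict[str, BaseCounts]
    cr_repeat_unit: str
    cr_repeat_copies: int


# ---------------------------------------------------------------------------
# probability helpers


def probs_from(at: float, s_at: float, s_gc: float) -> np.ndarray:
    """Plus-strand base probabilities (A, C, G, T) from composition targets."""
    gc = 1.0 - at
    p = np.array([
        at * (1 + s_at) / 2,    # A
        gc * (1 - s_gc) / 2,    # C
        gc * (1 + s_gc) / 2,    # G
        at * (1 - s_at) / 2,    # T
    ])
    if np.any(p < 0) or np.any(p > 1) or not np.isclose(p.sum(), 1.0):
        raise GenerationError(
            f"infeasible composition targets at={at}, s_at={s_at}, "
            f"s_gc={s_gc}"
        )
    return p


def _complement_probs(p: np.ndarray) -> np.ndarray:
    # A<->T, C<->G
    return np.array([p[3], p[2], p[1], p[0]])


def _stop_mask() -> np.ndarray:
    mask = np.ones((4, 4, 4))
    for codon in STOP_CODONS:
        mask[tuple(_BASE_INDEX[b] for b in codon)] = 0.0
    return mask


_STOP_MASK = _stop_mask()


def _conditional_codon_distribution(
    targets: Sequence[np.ndarray], iterations: int = 200
) -> np.ndarray:
    """Joint distribution over non-stop codons whose per-position marginals
    match the targets (iterative proportional fitting on the stop-masked
    product distribution)."""
    qs = [np.array(t, dtype=float) for t in targets]
    for t in qs:
        if np.any(t >= 1.0 - 1e-12):
            raise GenerationError(
                "degenerate codon-position target (a base has probability 1)"
            )
    for _ in range(iterations):
        joint = np.einsum("i,j,k->ijk", *qs) * _STOP_MASK
        total = joint.sum()
        if total <= 0:
            raise GenerationError("codon targets leave no non-stop codons")
        joint /= total
        marginals = [joint.sum(axis=(1, 2)), joint.sum(axis=(0, 2)),
                     joint.sum(axis=(0, 1))]
        for p in range(3):
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(marginals[p] > 0, targets[p] / marginals[p], 0.0)
            qs[p] = qs[p] * ratio
            s = qs[p].sum()
            if s <= 0:
                raise GenerationError("codon-position calibration failed")
            qs[p] /= s
    joint = np.einsum("i,j,k->ijk", *qs) * _STOP_MASK
    return joint / joint.sum()


_CODON_STRINGS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def _draw_codons(rng: np.random.Generator, joint: np.ndarray, n: int
                 ) -> List[str]:
    flat = joint.reshape(64)
    idx = rng.choice(64, size=n, p=flat)
    return [_CODON_STRINGS[i] for i in idx]


def _draw_bases(rng: np.random.Generator, p: np.ndarray, n: int) -> str:
    idx = rng.choice(4, size=n, p=p)
    return "".join(_BASES[i] for i in idx)


# ---------------------------------------------------------------------------
# generation


def _validate_spec(spec: SyntheticSpec) -> None:
    for gene, length in spec.gene_lengths.items():
        if length <= 0:
            raise GenerationError(f"{gene}: non-positive length {length}")
    for gene in spec.gene_order.names():
        if gene not in spec.gene_lengths:
            raise GenerationError(f"{gene}: no length specified")
    for gene in PCG_NAMES:
        if gene not in spec.gene_lengths:
            continue
        stop = spec.stop_codons.get(gene, "TAA")
        tail = 0 if stop in ("TAA", "TAG") else len(stop)
        if stop not in ("TAA", "TAG", "T", "TA"):
            raise GenerationError(f"{gene}: unsupported stop spec {stop!r}")
        if (spec.gene_lengths[gene] - tail) % 3:
            raise GenerationError(
                f"{gene}: length {spec.gene_lengths[gene]} inconsistent "
                f"with stop type {stop!r}"
            )
        start = spec.start_codons.get(gene, "ATG")
        if not (len(start) == 3 and start[:2] == "AT"):
            raise GenerationError(f"{gene}: start codon {start!r} not ATN")
    for (up, down), gap in spec.junction_gaps.items():
        if gap < 0:
            limit = min(spec.gene_lengths.get(up, 10**9),
                        spec.gene_lengths.get(down, 10**9))
            if -gap >= limit:
                raise GenerationError(
                    f"overlap {up}-{down} of {-gap} bp exceeds gene length"
                )
    if not (0 < spec.at_fraction < 1) or not (0 < spec.cr_at_fraction < 1):
        raise GenerationError("A+T fractions must lie in (0, 1)")
    for s in (spec.at_skew_target, spec.gc_skew_target, spec.cr_at_skew,
              spec.cr_gc_skew):
        if not (-1 < s < 1):
            raise GenerationError("skew targets must lie in (-1, 1)")


def _layout(spec: SyntheticSpec) -> Tuple[List[GeneFeature], int]:
    """Assign plus-strand coordinates walking the circular order from
    position 1; the control region follows the last gene (rrnS in the
    ancestral order) and the final gap closes the circle back to the first
    gene."""
    order = list(spec.gene_order.genes)
    entries: List[Tuple[str, str]] = order + [(CR_NAME, "J")]
    gaps = spec.junction_gaps
    pos = 1
    placed: List[Tuple[str, str, int, int]] = []
    for k, (name, strand) in enumerate(entries):
        length = spec.gene_lengths[name]
        start = pos
        end = start + length - 1
        placed.append((name, strand, start, end))
        nxt = entries[(k + 1) % len(entries)][0]
        pos = end + 1 + gaps.get((name, nxt), 0)
    total = pos - 1  # closing gap returns to position 1 on the circle
    features = []
    for name, strand, start, end in placed:
        cls = gene_class_for_name(name) or "CR"
        features.append(GeneFeature(
            name=name, gene_class=cls, start=start, end=end, strand=strand,
            anticodon=TRNA_ANTICODONS.get(name),
        ))
    return features, total


def _pcg_sequence(rng: np.random.Generator, spec: SyntheticSpec, gene: str,
                  joint: np.ndarray) -> str:
    length = spec.gene_lengths[gene]
    start = spec.start_codons.get(gene, "ATG")
    stop = spec.stop_codons.get(gene, "TAA")
    if stop in ("TAA", "TAG"):
        n_body = length // 3 - 2
        tail = stop
    else:
        n_body = (length - 3 - len(stop)) // 3
        tail = stop
    if n_body < 0:
        raise GenerationError(f"{gene}: too short for start+stop")
    body = "".join(_draw_codons(rng, joint, n_body))
    return start + body + tail


def generate(spec: SyntheticSpec) -> Tuple[MitoGenome, GroundTruth]:
    """Generate a genome and its realized ground truth, deterministically
    for a given ``spec.seed``."""
    _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    features, L = _layout(spec)

    # --- ownership map: who finally writes each plus-strand position -----
    # priority: PCG > CR > tRNA/rRNA > spacer background
    PRIO = {"PCG": 3, "CR": 2, "rRNA": 1, "tRNA": 1}
    owner = np.zeros(L, dtype=np.int8)  # 0 = spacer
    for f in features:
        idx = np.arange(f.start - 1, f.start - 1 + f.end - f.start + 1) % L
        owner[idx] = np.maximum(owner[idx], PRIO[f.gene_class])
    n_pcg = int((owner == 3).sum())
    n_cr = int((owner == 2).sum())
    n_rest = int((owner <= 1).sum())

    # --- solve the rest-of-genome composition so the whole-genome mixture
    # hits the global targets -------------------------------------------
    p1, p2, p3 = spec.pcg_position_at
    at_pcg = (p1 + p2 + p3) / 3
    at_t, s_at, s_gc = spec.at_fraction, spec.at_skew_target, spec.gc_skew_target
    if n_rest == 0:
        raise GenerationError("layout leaves no non-PCG, non-CR sequence")
    at_rest = (at_t * L - at_pcg * n_pcg - spec.cr_at_fraction * n_cr) / n_rest
    if not (0.005 < at_rest < 0.995):
        raise GenerationError(
            f"infeasible whole-genome A+T target: rest regions would need "
            f"A+T {at_rest:.3f}"
        )
    # skew balance over A/T (resp. G/C) bases
    nat_tot, nat_pcg = at_t * L, at_pcg * n_pcg
    nat_cr, nat_rest = spec.cr_at_fraction * n_cr, at_rest * n_rest
    s_at_rest = ((s_at * nat_tot - s_at * nat_pcg - spec.cr_at_skew * nat_cr)
                 / nat_rest)
    ngc_tot = (1 - at_t) * L
    ngc_pcg, ngc_cr = (1 - at_pcg) * n_pcg, (1 - spec.cr_at_fraction) * n_cr
    ngc_rest = (1 - at_rest) * n_rest
    s_gc_rest = ((s_gc * ngc_tot - s_gc * ngc_pcg - spec.cr_gc_skew * ngc_cr)
                 / ngc_rest)
    if not (-1 < s_at_rest < 1 and -1 < s_gc_rest < 1):
        raise GenerationError("infeasible skew targets for rest regions")

    p_rest = probs_from(at_rest, s_at_rest, s_gc_rest)
    p_cr = probs_from(spec.cr_at_fraction, spec.cr_at_skew, spec.cr_gc_skew)
    pos_targets_J = [probs_from(a, s_at, s_gc) for a in (p1, p2, p3)]
    joint_J = _conditional_codon_distribution(pos_targets_J)
    # N-strand genes: coding-sense draws use complemented ratios so the
    # deposited plus strand keeps the global skew
    pos_targets_N = [_complement_probs(t) for t in pos_targets_J]
    joint_N = _conditional_codon_distribution(pos_targets_N)

    # --- draw and assemble ----------------------------------------------
    plus = np.array(list(_draw_bases(rng, p_rest, L)))  # spacer background

    def write(f: GeneFeature, plus_seq: str) -> None:
        idx = np.arange(f.start - 1, f.start - 1 + len(plus_seq)) % L
        plus[idx] = list(plus_seq)

    def revcomp(s: str) -> str:
        return "".join(_COMPLEMENT[b] for b in reversed(s))

    cr_unit = ""
    by_class = sorted(features, key=lambda f: PRIO[f.gene_class])
    for f in by_class:
        glen = f.end - f.start + 1
        if f.gene_class in ("tRNA", "rRNA"):
            write(f, _draw_bases(rng, p_rest, glen))
        elif f.gene_class == "CR":
            cr_unit = _draw_bases(rng, p_cr, min(spec.cr_repeat_unit_bp, glen))
            repeats = (cr_unit * spec.cr_repeat_copies)[:glen]
            filler = _draw_bases(rng, p_cr, max(0, glen - len(repeats)))
            write(f, repeats + filler)
        else:  # PCG
            joint = joint_J if f.strand == "J" else joint_N
            coding = _pcg_sequence(rng, spec, f.name, joint)
            write(f, coding if f.strand == "J" else revcomp(coding))

    genome = MitoGenome(
        record_id=spec.record_id, organism=spec.organism,
        sequence="".join(plus), circular=True, features=features,
        source="synthetic",
    )
    if spec.cr_wraps_origin:
        # rotate so the CR midpoint sits on the origin
        from .architecture import rotate_origin

        cr = next(f for f in features if f.gene_class == "CR")
        genome = rotate_origin(genome, cr.start + (cr.end - cr.start + 1) // 2)

    # --- realized ground truth (direct counting, independent of the
    # analysis modules) ---------------------------------------------------
    codon_counts: Counter = Counter()
    starts: Dict[str, str] = {}
    stops: Dict[str, str] = {}
    region_seqs: Dict[str, List[str]] = {
        "whole": [genome.sequence], "PCGs": [], "rrnL": [], "rrnS": [],
        "tRNA": [], "CR": [],
    }
    for f in genome.features:
        coding = extract_feature_sequence(genome, f)
        if f.gene_class == "PCG":
            region_seqs["PCGs"].append(coding)
            starts[f.name] = coding[:3]
            stop_spec = spec.stop_codons.get(f.name, "TAA")
            if stop_spec in ("TAA", "TAG"):
                if coding[-3:] != stop_spec:
                    raise GenerationError(
                        f"{f.name}: assembly corrupted the stop codon"
                    )
                stops[f.name] = stop_spec
                codons = [coding[i:i + 3] for i in range(0, len(coding) - 3, 3)]
            else:
                stops[f.name] = stop_spec + "-"
                n = (len(coding) - len(stop_spec)) // 3
                codons = [coding[3 * i:3 * i + 3] for i in range(n)]
            if coding[:2] != "AT":
                raise GenerationError(
                    f"{f.name}: assembly corrupted the start codon"
                )
            if any(c in STOP_CODONS for c in codons):
                raise GenerationError(f"{f.name}: internal stop codon drawn")
            codon_counts.update(codons)
        elif f.name in ("rrnL", "rrnS"):
            region_seqs[f.name].append(coding)
        elif f.gene_class == "tRNA":
            region_seqs["tRNA"].append(coding)
        else:
            region_seqs["CR"].append(coding)

    def _counts(seqs: List[str]) -> BaseCounts:
        c = Counter("".join(seqs))
        return BaseCounts(c.get("A", 0), c.get("C", 0), c.get("G", 0),
                          c.get("T", 0), 0)

    region_counts = {k: _counts(v) for k, v in region_seqs.items() if v}
    lengths = {f.name: f.length(L) for f in genome.features}
    truth = GroundTruth(
        genome_length=L,
        gene_order=spec.gene_order,
        strands={f.name: f.strand for f in genome.features},
        gene_lengths=lengths,
        junction_gaps=dict(spec.junction_gaps),
        start_codons=starts,
        stop_codons=stops,
        codon_counts=codon_counts,
        total_nonstop_codons=sum(codon_counts.values()),
        region_counts=region_counts,
        cr_repeat_unit=cr_unit,
        cr_repeat_copies=spec.cr_repeat_copies,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# synthetic tRNA structures


@dataclass
class StructureGroundTruth:
    arms: Dict[str, Dict[str, bool]]
    gu_counts: Dict[str, int]
    pair_counts: Dict[str, int]

    @property
    def total_gu(self) -> int:
        return sum(self.gu_counts.values())


def _build_cloverleaf(rng: np.random.Generator, name: str, length: int,
                      drop_arm: Optional[str], gu_rate: float,
                      p_loop: np.ndarray) -> Tuple[CloverleafStructure, int]:
    """One synthetic cloverleaf of approximately the requested length.

    Layout 5'->3': acceptor(7) link DHU(4bp stem) link anticodon(5bp stem,
    7nt loop) variable-loop TψC(5bp stem) acceptor(7) tail. A dropped arm is
    replaced by an unpaired loop.
    """
    acc, dhu_s, ac_s, tpc_s = 7, 4, 5, 5
    dhu_loop, ac_loop, tpc_loop = 7, 7, 7
    link1, link2, var, tail = 2, 1, 4, 1
    drop_loop = 6  # unpaired run replacing a dropped arm

    def total() -> int:
        t = 2 * acc + link1 + link2 + var + tail
        t += (2 * dhu_s + dhu_loop) if drop_arm != "DHU" else drop_loop
        t += 2 * ac_s + ac_loop
        t += (2 * tpc_s + tpc_loop) if drop_arm != "TpsiC" else drop_loop
        return t

    # absorb the length difference into the flexible loops
    for _ in range(64):
        diff = length - total()
        if diff == 0:
            break
        if diff > 0:
            var += 1
        elif var > 2:
            var -= 1
        elif dhu_loop > 4 and drop_arm != "DHU":
            dhu_loop -= 1
        elif tpc_loop > 4 and drop_arm != "TpsiC":
            tpc_loop -= 1
        elif tail > 0:
            tail -= 1
        else:
            break  # shortest representable cloverleaf reached

    seq: List[str] = []
    pairs: List[Tuple[int, int]] = []
    gu_injected = 0

    def draw_loop(n: int) -> None:
        seq.extend(_BASES[i] for i in rng.choice(4, size=n, p=p_loop))

    def open_stem(n: int) -> List[int]:
        opens = []
        for _ in range(n):
            seq.append("?")  # placeholder, assigned at close time
            opens.append(len(seq))
        return opens

    def close_stem(opens: List[int]) -> None:
        nonlocal gu_injected
        for pos5 in reversed(opens):
            pos3 = len(seq) + 1
            if rng.random() < gu_rate:
                b5, b3 = ("G", "T") if rng.random() < 0.5 else ("T", "G")
                gu_injected += 1
            else:
                b5 = _BASES[rng.choice(4)]
                b3 = _COMPLEMENT[b5]
            seq[pos5 - 1] = b5
            seq.append(b3)
            pairs.append((pos5, pos3))

    acc_open = open_stem(acc)
    draw_loop(link1)
    if drop_arm == "DHU":
        draw_loop(drop_loop)
    else:
        d_open = open_stem(dhu_s)
        draw_loop(dhu_loop)
        close_stem(d_open)
    draw_loop(link2)
    a_open = open_stem(ac_s)
    draw_loop(ac_loop)
    close_stem(a_open)
    draw_loop(var)
    if drop_arm == "TpsiC":
        draw_loop(drop_loop)
    else:
        t_open = open_stem(tpc_s)
        draw_loop(tpc_loop)
        close_stem(t_open)
    close_stem(acc_open)
    draw_loop(tail)

    structure = CloverleafStructure(
        trna_name=name,
        sequence="".join(seq).replace("T", "U"),
        pairs=sorted(pairs),
    )
    return structure, gu_injected


def _install_anticodon(structure: CloverleafStructure, anticodon: str) -> None:
    """Write the biological anticodon into the middle of the anticodon loop."""
    from .trna import classify_arms

    classify_arms(structure)
    arm = structure.arms.get("anticodon")
    if arm is None or not arm.present or arm.loop_length < 7:
        return
    innermost = max(arm.pair_indices, key=lambda p: p[0])
    mid = (innermost[0] + 1 + innermost[1] - 1) // 2
    seq = list(structure.sequence)
    seq[mid - 2:mid + 1] = list(anticodon.replace("T", "U"))
    structure.sequence = "".join(seq)
    structure.anticodon_triplet = anticodon.replace("T", "U")


def generate_trna_structures(
    trna_lengths: Optional[Dict[str, int]] = None,
    dropout: Optional[Dict[str, str]] = None,
    gu_rate: float = 0.1,
    seed: int = 0,
) -> Tuple[List[CloverleafStructure], StructureGroundTruth]:
    """Synthetic cloverleaf structures for the 22 tRNAs.

    ``dropout`` maps tRNA name -> arm ("DHU" or "TpsiC") to remove; by
    default trnS1 loses its DHU arm, as in virtually all animal
    mitogenomes. ``gu_rate`` is the per-pair probability of a G-U wobble.
    """
    if trna_lengths is None:
        trna_lengths = dict(DEFAULT_TRNA_LENGTHS)
    if dropout is None:
        dropout = {"trnS1": "DHU"}
    for name, arm in dropout.items():
        if name not in TRNA_NAMES or arm not in ("DHU", "TpsiC"):
            raise ValueError(f"invalid dropout entry {name!r}: {arm!r}")
    rng = np.random.default_rng(seed)
    p_loop = probs_from(0.80, 0.0, 0.0)
    structures: List[CloverleafStructure] = []
    arms_truth: Dict[str, Dict[str, bool]] = {}
    gu_counts: Dict[str, int] = {}
    pair_counts: Dict[str, int] = {}
    for name in TRNA_NAMES:
        if name not in trna_lengths:
            continue
        drop = dropout.get(name)
        s, gu = _build_cloverleaf(rng, name, trna_lengths[name], drop,
                                  gu_rate, p_loop)
        _install_anticodon(s, TRNA_ANTICODONS[name])
        structures.append(s)
        arms_truth[name] = {
            "acceptor": True,
            "DHU": drop != "DHU",
            "anticodon": True,
            "TpsiC": drop != "TpsiC",
        }
        gu_counts[name] = gu
        pair_counts[name] = len(s.pairs)
    return structures, StructureGroundTruth(
        arms=arms_truth, gu_counts=gu_counts, pair_counts=pair_counts,
    )


__all__ = [
    "SyntheticSpec", "GroundTruth", "StructureGroundTruth",
    "GenerationError", "generate", "generate_trna_structures", "probs_from",
    "DEFAULT_GENE_LENGTHS", "DEFAULT_PCG_LENGTHS", "DEFAULT_TRNA_LENGTHS",
    "DEFAULT_JUNCTION_GAPS", "DEFAULT_START_CODONS", "DEFAULT_STOP_CODONS",
    "TRNA_ANTICODONS",
]
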