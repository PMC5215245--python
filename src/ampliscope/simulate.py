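"""Ground-truthed amplicon dataset simulation.

Pipeline: a weighted community design allocates a read budget across
genomes (largest-remainder, deterministic); each read draws one of its
genome's 16S amplicon copies uniformly; an Ion Torrent-style error model
corrupts it (indels + substitutions at per-base rates, error probability
ramping toward the 3' end, read length normally distributed around the
amplicon size); the result is a FASTQ plus a per-read truth table.

Reproducibility contract: one master seed; each read gets its own child RNG
stream derived from (seed, read index), so output is byte-identical across
runs and independent of chunking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon import Amplicon, PrimerPair, find_amplicons
from .exceptions import InputError

logger = logging.getLogger(__name__)

#: Community complexity labels: one dominant species / four dominant
#: species in three families / all genomes equal.
COMPLEXITY_LABELS = ("LC", "MC", "HC", "custom")

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class CommunityDesign:
    """Weighted genome composition of a mock community."""

    entries: tuple[tuple[str, float], ...]
    complexity_label: str = "custom"

    def __post_init__(self):
        if not self.entries:
            raise InputError("community design has no entries")
        weights = [w for _, w in self.entries]
        if any(w < 0 for w in weights):
            raise InputError("negative weight in community design")
        if not any(w > 0 for w in weights):
            raise InputError("all community weights are zero")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise InputError(f"community weights sum to {sum(weights)}, expected 1")
        if self.complexity_label not in COMPLEXITY_LABELS:
            raise InputError(f"unknown complexity label {self.complexity_label!r}")

    @property
    def genome_ids(self) -> list[str]:
        return [g for g, _ in self.entries]


def lc_design(genome_ids: list[str], dominant: str, dominant_weight: float = 0.30) -> CommunityDesign:
    """Low complexity: one dominant genome, the rest equally distributed."""
    others = [g for g in genome_ids if g != dominant]
    if dominant not in genome_ids or not others:
        raise InputError("LC design needs the dominant genome plus at least one other")
    w = (1.0 - dominant_weight) / len(others)
    entries = [(g, dominant_weight if g == dominant else w) for g in sorted(genome_ids)]
    return CommunityDesign(tuple(entries), "LC")


def mc_design(genome_ids: list[str], dominants: list[str], dominant_weight: float = 0.20) -> CommunityDesign:
    """Medium complexity: four dominant genomes at 20% each, rest equal."""
    others = [g for g in genome_ids if g not in dominants]
    if len(dominants) * dominant_weight >= 1.0 or not others:
        raise InputError("MC dominants leave no mass for the remaining genomes")
    if set(dominants) - set(genome_ids):
        raise InputError("MC dominant not present in genome list")
    w = (1.0 - len(dominants) * dominant_weight) / len(others)
    entries = [(g, dominant_weight if g in dominants else w) for g in sorted(genome_ids)]
    return CommunityDesign(tuple(entries), "MC")


def hc_design(genome_ids: list[str]) -> CommunityDesign:
    """High complexity: no dominant genome, all equally distributed."""
    if not genome_ids:
        raise InputError("HC design needs at least one genome")
    w = 1.0 / len(genome_ids)
    return CommunityDesign(tuple((g, w) for g in sorted(genome_ids)), "HC")


def allocate_reads(design: CommunityDesign, n_reads: int) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of *n_reads* over weights.

    Counts sum exactly to *n_reads*; remainder ties break by genome_id
    lexicographic order, so the allocation is reproducible without an RNG.
    """
    if n_reads < 1:
        raise InputError("n_reads must be positive")
    ids = [g for g, _ in design.entries]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate genome_id in design")
    quotas = {g: w * n_reads for g, w in design.entries}
    counts = {g: int(np.floor(q + 1e-9)) for g, q in quotas.items()}
    leftover = n_reads - sum(counts.values())
    # Largest remainder first; ties by id. Zero-remainder genomes are never
    # reached because leftover <= number of fractional quotas.
    order = sorted(ids, key=lambda g: (-(quotas[g] - counts[g]), g))
    for g in order[:leftover]:
        counts[g] += 1
    assert sum(counts.values()) == n_reads
    return counts


@dataclass(frozen=True)
class ErrorModelParams:
    """Per-base rates and read-length spread for the sequencing error model.

    Defaults are the Ion Torrent profile used throughout the protocol:
    1% deletions, 0.5% insertions, 0.5% substitutions, 20 bp read-length
    standard deviation around the amplicon size.  ``end_bias`` controls a
    linear ramp of error probability toward the 3' end (0 = uniform); the
    ramp is mean-normalized so realized rates match the nominal ones.
    """

    deletion_rate: float = 0.01
    insertion_rate: float = 0.005
    substitution_rate: float = 0.005
    length_sd: float = 20.0
    end_bias: float = 1.0

    def __post_init__(self):
        rates = (self.deletion_rate, self.insertion_rate, self.substitution_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise InputError("error rates must lie in [0, 1]")
        if sum(rates) > 1.0:
            raise InputError("deletion + insertion + substitution rates exceed 1")
        if self.length_sd < 0:
            raise InputError("length_sd must be non-negative")
        if self.end_bias < 0:
            raise InputError("end_bias must be non-negative")


ERROR_FREE = ErrorModelParams(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ErrorEvents:
    """Realized event counts for one simulated read.

    ``n_template_bases`` is the number of bases the per-base model was
    applied to (the read's template length after the length draw), i.e. the
    denominator for realized per-base rates.
    """

    n_deletions: int
    n_insertions: int
    n_substitutions: int
    n_template_bases: int


def _position_weights(n: int, end_bias: float) -> np.ndarray:
    """Linear 5'->3' ramp with mean exactly 1 over the read."""
    if end_bias == 0.0 or n == 1:
        return np.ones(n)
    ramp = 1.0 + end_bias * np.arange(n) / (n - 1)
    return ramp / (1.0 + end_bias / 2.0)


def apply_error_model(
    sequence: str,
    params: ErrorModelParams,
    rng: np.random.Generator,
) -> tuple[str, ErrorEvents]:
    """Corrupt one amplicon into a simulated read.

    The read's template length is drawn from Normal(len(sequence),
    length_sd) and rounded; shorter targets truncate the amplicon from the
    3' end, longer targets read through the template end into uniform
    random bases (adapter read-through), so the realized length spread is
    two-sided.  Per-base events are then drawn independently and
    exclusively per position: deletion, 1-base insertion after the
    position, or substitution to one of the 3 alternative bases, with
    probability rate * w(i) where w is the mean-normalized 3' ramp.
    """
    if not sequence:
        raise InputError("cannot simulate a read from an empty sequence")
    n0 = len(sequence)
    if params.length_sd > 0:
        target = max(1, round(rng.normal(n0, params.length_sd)))
    else:
        target = n0
    codes = _CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    if target <= n0:
        codes = codes[:target]
    else:
        codes = np.concatenate([codes, rng.integers(0, 4, size=target - n0, dtype=np.uint8)])
    n = len(codes)

    total_rate = params.deletion_rate + params.insertion_rate + params.substitution_rate
    if total_rate == 0.0:
        return _decode(codes, sequence, target, n0), ErrorEvents(0, 0, 0, n)

    w = _position_weights(n, params.end_bias)
    u = rng.random(n)
    p_del = params.deletion_rate * w
    p_ins = p_del + params.insertion_rate * w
    p_sub = p_ins + params.substitution_rate * w
    del_mask = u < p_del
    ins_mask = (~del_mask) & (u < p_ins)
    sub_mask = (~del_mask) & (~ins_mask) & (u < p_sub)

    out_codes = codes.copy()
    n_sub = int(sub_mask.sum())
    if n_sub:
        orig = codes[sub_mask]
        shift = rng.integers(1, 4, size=n_sub, dtype=np.uint8)
        subs = (orig + shift) % 4
        # 'N' positions substitute to a uniform concrete base
        subs[orig == 4] = rng.integers(0, 4, size=int((orig == 4).sum()), dtype=np.uint8)
        out_codes[sub_mask] = subs

    contrib = np.ones(n, dtype=np.int64)
    contrib[del_mask] = 0
    contrib[ins_mask] = 2
    starts = np.cumsum(contrib) - contrib
    out = np.empty(int(contrib.sum()), dtype=np.uint8)
    keep = ~del_mask
    out[starts[keep]] = out_codes[keep]
    n_ins = int(ins_mask.sum())
    if n_ins:
        out[starts[ins_mask] + 1] = rng.integers(0, 4, size=n_ins, dtype=np.uint8)

    read = _BASES[out].tobytes().decode("ascii")
    return read, ErrorEvents(int(del_mask.sum()), n_ins, n_sub, n)


def _decode(codes: np.ndarray, original: str, target: int, n0: int) -> str:
    # Error-free fast path: preserve the original string (incl. any 'N')
    # when no truncation/extension happened.
    if target == n0:
        return original.upper()
    return _BASES[codes].tobytes().decode("ascii")


#: Truth-table column order (internal, 0-based half-open coordinates).
TRUTH_COLUMNS = (
    "read_id", "genome_id", "taxid", "start", "end", "strand",
    "n_del", "n_ins", "n_sub",
)


@dataclass
class SimulatedDataset:
    """Output bundle of :func:`simulate_dataset`."""

    fastq_path: Path
    truth: pd.DataFrame
    dropped_genomes: list[str] = field(default_factory=list)


def _read_rng(seed: int, read_index: int) -> np.random.Generator:
    """Per-read child stream: reproducible and chunking-independent."""
    return np.random.default_rng([seed, read_index])


def simulate_dataset(
    genomes: dict[str, str],
    genome_taxids: dict[str, int],
    design: CommunityDesign,
    primers: PrimerPair,
    n_reads: int,
    params: ErrorModelParams,
    seed: int,
    out_fastq: str | Path,
) -> SimulatedDataset:
    """Simulate one ground-truthed amplicon dataset.

    Genomes with positive weight that yield no amplicon are dropped with a
    warning and the remaining weights renormalized (this is how primer pairs
    that fail to amplify some community members behave).  Each read picks
    one of its genome's amplicon copies uniformly, then passes through the
    error model.  FASTQ qualities are a constant 'I' (Q40) placeholder —
    the evaluation protocol never consumes them.
    """
    if n_reads < 1:
        raise InputError("n_reads must be positive")

    amplicons: dict[str, list[Amplicon]] = {}
    dropped: list[str] = []
    kept_entries: list[tuple[str, float]] = []
    for genome_id, weight in design.entries:
        if weight <= 0:
            continue
        if genome_id not in genomes:
            raise InputError(f"designed genome {genome_id!r} missing from FASTA collection")
        hits = find_amplicons(genome_id, genomes[genome_id], primers)
        if hits:
            amplicons[genome_id] = hits
            kept_entries.append((genome_id, weight))
        else:
            dropped.append(genome_id)
            logger.warning("genome %s yields no amplicon with primers %s; dropped", genome_id, primers.name)
    if not kept_entries:
        raise InputError("no designed genome amplifies with the given primers")
    total_w = sum(w for _, w in kept_entries)
    effective = CommunityDesign(
        tuple((g, w / total_w) for g, w in kept_entries), design.complexity_label
    )
    counts = allocate_reads(effective, n_reads)

    out_fastq = Path(out_fastq)
    out_fastq.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    read_index = 0
    with open(out_fastq, "w") as fq:
        for genome_id in sorted(counts):
            taxid = genome_taxids[genome_id]
            copies = amplicons[genome_id]
            for _ in range(counts[genome_id]):
                rng = _read_rng(seed, read_index)
                amp = copies[int(rng.integers(0, len(copies)))]
                read, events = apply_error_model(amp.sequence, params, rng)
                read_id = f"read_{read_index:07d}"
                fq.write(f"@{read_id}\n{read}\n+\n{'I' * len(read)}\n")
                rows.append(
                    (read_id, genome_id, taxid, amp.start, amp.end, amp.strand,
                     events.n_deletions, events.n_insertions, events.n_substitutions)
                )
                read_index += 1
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return SimulatedDataset(out_fastq, truth, dropped)
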