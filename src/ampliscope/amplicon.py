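"""In-silico PCR: exact degenerate-primer matching and amplicon extraction.

Primer sites must match exactly (IUPAC degeneracy expanded, zero mismatches),
mirroring amplification of a mock community where any genome lacking a
perfect primer site simply fails to amplify.  Products are primer-inclusive,
so the familiar "~200 bp" / "~400 bp" 16S amplicon sizes refer to the full
primer-to-primer span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .exceptions import InputError

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

#: Default cap on product length; guards against runaway reverse-site matches.
MAX_PRODUCT_LENGTH = 5000


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair, both strings written 5'->3' as synthesized.

    ``reverse`` anneals to the forward strand's complement, i.e. its
    reverse complement is what appears on the forward strand downstream of
    the forward site.
    """

    forward: str
    reverse: str
    name: str = "unnamed"

    def __post_init__(self):
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise InputError(f"{label} primer is empty")
            bad = set(seq.upper()) - set(IUPAC)
            if bad:
                raise InputError(f"{label} primer contains non-IUPAC codes: {sorted(bad)}")


@dataclass(frozen=True)
class Amplicon:
    """A primer-delimited product on a genome.

    Coordinates are 0-based half-open on the genome's forward strand;
    ``sequence`` is the product read 5'->3' on *strand* and includes both
    primer sites.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(f"bad amplicon coordinates [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise InputError("amplicon sequence length disagrees with coordinates")

    def __len__(self) -> int:
        return self.end - self.start


def iupac_regex(primer: str) -> re.Pattern:
    """Compile a degenerate primer into an exact-match regex."""
    parts = []
    for code in primer.upper():
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_strand(
    genome_id: str,
    seq: str,
    primers: PrimerPair,
    strand: str,
    genome_length: int,
    max_product_length: int,
) -> list[Amplicon]:
    """One-strand scan: forward primer site, then the nearest downstream
    reverse-complemented reverse-primer site within the length cap (the
    shortest valid product per forward site)."""
    fwd_re = iupac_regex(primers.forward)
    rev_site_re = iupac_regex(revcomp(primers.reverse))
    out = []
    for m in fwd_re.finditer(seq):
        window_end = min(len(seq), m.start() + max_product_length)
        hit = rev_site_re.search(seq, m.end(), window_end)
        if hit is None:
            continue
        s, e = m.start(), hit.end()
        if strand == "+":
            start, end = s, e
        else:  # map coordinates on the reverse strand back to forward
            start, end = genome_length - e, genome_length - s
        out.append(Amplicon(genome_id, start, end, strand, seq[s:e]))
    return out


def find_amplicons(
    genome_id: str,
    genome_seq: str,
    primers: PrimerPair,
    max_product_length: int = MAX_PRODUCT_LENGTH,
) -> list[Amplicon]:
    """Find every exact-match amplicon on either strand of a genome.

    No primer mismatches are tolerated; a genome without a perfect site on
    either strand returns an empty list (it "does not amplify").  Results
    are sorted by forward-strand start coordinate.
    """
    seq = str(genome_seq).upper()
    n = len(seq)
    hits = _scan_strand(genome_id, seq, primers, "+", n, max_product_length)
    hits += _scan_strand(genome_id, revcomp(seq), primers, "-", n, max_product_length)
    # A perfectly palindromic product would be reported once per strand;
    # deduplicate on coordinates.
    seen: set[tuple[int, int, str]] = set()
    uniq = []
    for a in sorted(hits, key=lambda a: (a.start, a.end, a.strand)):
        key = (a.start, a.end, a.sequence)
        if key not in seen:
            seen.add(key)
            uniq.append(a)
    return uniq
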