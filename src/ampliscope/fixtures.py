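"""Synthetic marker-bearing genomes plus a toy taxonomy.

Stands in for a downloadable mock-community genome set so the whole
protocol is testable offline: each synthetic genome embeds 1..k copies of a
marker gene built as conserved primer sites flanking a taxon-specific
variable region.  Variable regions diverge more across families than within
genera (family sequences are independent random draws; genera mutate the
family sequence; species mutate the genus sequence), loosely mimicking 16S
hypervariable-region structure.

Everything in this module is synthetic; it makes no claim about any real
organism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .amplicon import PrimerPair, revcomp
from .exceptions import InputError
from .taxonomy import TaxNode, TaxonomyTree

#: Built-in primer pair for fixture markers (forward primer carries one
#: degenerate code so IUPAC expansion is exercised end to end).
FIXTURE_PRIMERS = PrimerPair(
    forward="ACTCCTACGGRAGGCAGCAG",
    reverse="ATTACCGCGGCTGCTGG",
    name="fixture~200",
)

_VARIABLE_LENGTH = 160           # marker variable region, nt
_GENUS_DIVERGENCE = 0.12         # fraction of variable sites mutated per genus
_SPECIES_DIVERGENCE = 0.03       # further mutated per species
_ALPHABET = np.array(list("ACGT"))


@dataclass
class FixtureCollection:
    """Bundle returned by :func:`generate_fixture_collection`."""

    genomes: dict[str, str]
    taxonomy: TaxonomyTree
    species_taxids: dict[str, int]   # genome_id -> species taxid
    primers: PrimerPair
    marker_copies: dict[str, int]    # genome_id -> embedded marker copies

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write genomes.fasta, taxonomy.tsv and genome_taxids.tsv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "genomes.fasta"
        with open(fasta, "w") as fh:
            for gid in sorted(self.genomes):
                seq = self.genomes[gid]
                fh.write(f">{gid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        tax = out_dir / "taxonomy.tsv"
        self.taxonomy.write_tsv(tax)
        mapping = out_dir / "genome_taxids.tsv"
        with open(mapping, "w") as fh:
            fh.write("genome_id\ttaxid\n")
            for gid in sorted(self.species_taxids):
                fh.write(f"{gid}\t{self.species_taxids[gid]}\n")
        return {"fasta": fasta, "taxonomy": tax, "genome_taxids": mapping}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, fraction: float) -> str:
    arr = np.array(list(seq))
    n_mut = max(1, round(fraction * len(arr)))
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def generate_fixture_collection(
    n_families: int = 3,
    genera_per_family: int = 2,
    species_per_genus: int = 2,
    copies_range: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> FixtureCollection:
    """Build synthetic genomes and a consistent toy taxonomy.

    One genome per species; each genome embeds a number of identical marker
    copies drawn uniformly from ``copies_range`` (inclusive), separated by
    random spacer sequence.  The marker is recoverable with
    :data:`FIXTURE_PRIMERS` and exact matching.  Different seeds change the
    variable-region content and spacers but never the topology.
    """
    if min(n_families, genera_per_family, species_per_genus) < 1:
        raise InputError("all fixture counts must be >= 1")
    lo, hi = copies_range
    if not (1 <= lo <= hi):
        raise InputError("copies_range must satisfy 1 <= lo <= hi")

    rng = np.random.default_rng(seed)
    fwd_site = FIXTURE_PRIMERS.forward.replace("R", "A")  # concrete instance of the degenerate code
    rev_site = revcomp(FIXTURE_PRIMERS.reverse)

    nodes: dict[int, TaxNode] = {1: TaxNode(1, 1, "no rank", "root")}
    genomes: dict[str, str] = {}
    species_taxids: dict[str, int] = {}
    marker_copies: dict[str, int] = {}

    next_id = 2
    for f in range(n_families):
        fam_id = next_id
        next_id += 1
        nodes[fam_id] = TaxNode(fam_id, 1, "family", f"Family{f + 1:02d}")
        fam_seq = _random_seq(rng, _VARIABLE_LENGTH)
        for g in range(genera_per_family):
            gen_id = next_id
            next_id += 1
            nodes[gen_id] = TaxNode(gen_id, fam_id, "genus", f"Genus{f + 1:02d}{chr(97 + g)}")
            gen_seq = _mutate(rng, fam_seq, _GENUS_DIVERGENCE)
            for s in range(species_per_genus):
                sp_id = next_id
                next_id += 1
                name = f"Species{f + 1:02d}{chr(97 + g)}{s + 1}"
                nodes[sp_id] = TaxNode(sp_id, gen_id, "species", name)
                sp_seq = _mutate(rng, gen_seq, _SPECIES_DIVERGENCE)
                marker = fwd_site + sp_seq + rev_site
                k = int(rng.integers(lo, hi + 1))
                parts = [_random_seq(rng, int(rng.integers(200, 401)))]
                for _ in range(k):
                    parts.append(marker)
                    parts.append(_random_seq(rng, int(rng.integers(200, 401))))
                gid = f"genome_{name}"
                genomes[gid] = "".join(parts)
                species_taxids[gid] = sp_id
                marker_copies[gid] = k

    return FixtureCollection(
        genomes=genomes,
        taxonomy=TaxonomyTree(nodes),
        species_taxids=species_taxids,
        primers=FIXTURE_PRIMERS,
        marker_copies=marker_copies,
    )
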