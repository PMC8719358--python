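"""Transgene barcode registry.

Retrograde viruses deliver a transgene (a recombinase such as Cre or FLPo, a
fluorophore such as GFP or tdTomato) whose mRNA acts as a sequence barcode for
the injection target. To quantify those barcodes, the transgene sequences are
appended to the host reference genome as extra contigs with a matching gene
annotation, and an external aligner (e.g. Cell Ranger) does the rest.

This module holds the registry of transgene sequences, writes the augmented
reference (FASTA + GTF), and quantifies how discriminable two barcodes are —
homologous transgenes (two Cre isoforms, say) must differ enough at the read
scale that reads never cross-align.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .errors import FormatError, RegistryError

_VALID_BASES = frozenset("ACGTN")

#: Alignment scoring used for percent identity: match +1, mismatch -1,
#: linear gap penalty -2. Identity = matches / alignment length (gaps count
#: toward the length, never as matches). N never counts as a match.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_SCORE = -2.0

#: Default k-mer length for the discriminability screen — on the order of a
#: sequencing read, because read-level misassignment is what matters.
DEFAULT_K = 90


@dataclass
class TransgeneRecord:
    """One viral transgene barcode.

    Parameters
    ----------
    name
        Unique identifier (FASTA header token before the first whitespace).
    sequence
        Nucleotide sequence over A/C/G/T; ``N`` is tolerated but flagged and
        never counts as an alignment match.
    projection_target
        Free-text label for the injected structure (optional metadata).
    virus_class
        Free-text label, e.g. ``"AAVrg"`` or ``"HSV"``.
    has_wpre
        Whether the construct carries the 3' WPRE element (metadata only;
        it motivates 5' sequencing but has no computational role here).
    """

    name: str
    sequence: str
    projection_target: str = ""
    virus_class: str = ""
    has_wpre: bool = False
    contains_n: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise RegistryError("transgene name must be nonempty")
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise RegistryError(f"transgene {self.name!r} has empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise RegistryError(
                f"transgene {self.name!r} contains invalid characters {sorted(bad)}"
            )
        self.contains_n = "N" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IdentityResult:
    """Pairwise similarity between two transgene barcodes."""

    pair: tuple[str, str]
    percent_identity: float
    aligned_length: int
    shared_kmer_fraction: float
    k: int


def parse_transgene_fasta(text: str) -> list[TransgeneRecord]:
    """Parse transgene records from FASTA text.

    One record per entry, order preserved; the header token before the first
    whitespace becomes the record name. Duplicate names or empty sequences
    are errors.
    """
    records: list[TransgeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        name = rec.id
        if not name:
            raise FormatError("FASTA entry with empty header")
        if name in seen:
            raise RegistryError(f"duplicate transgene name {name!r}")
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"FASTA entry {name!r} has empty sequence")
        records.append(TransgeneRecord(name=name, sequence=seq))
        seen.add(name)
    if not records and text.strip():
        raise FormatError("input is not valid FASTA (no entries parsed)")
    return records


def emit_augmented_reference(registry: list[TransgeneRecord]) -> tuple[str, str]:
    """Render a transgene registry as reference-augmentation files.

    Returns ``(fasta_text, gtf_text)``. Each transgene becomes one contig
    whose single gene/transcript/exon spans positions 1..len (1-based closed
    intervals, + strand), with ``gene_id`` and ``transcript_id`` equal to the
    record name — the layout aligners expect for custom references. Output is
    byte-stable for a given registry.
    """
    if not registry:
        raise RegistryError("cannot emit reference from an empty registry")
    names = [r.name for r in registry]
    if len(set(names)) != len(names):
        raise RegistryError("registry contains duplicate names")

    fasta_lines: list[str] = []
    gtf_lines: list[str] = []
    for rec in registry:
        fasta_lines.append(f">{rec.name}")
        for i in range(0, len(rec.sequence), 60):
            fasta_lines.append(rec.sequence[i : i + 60])
        attrs = f'gene_id "{rec.name}"; transcript_id "{rec.name}";'
        for feature in ("gene", "transcript", "exon"):
            gtf_lines.append(
                "\t".join(
                    [
                        rec.name,
                        "retrotag",
                        feature,
                        "1",
                        str(len(rec.sequence)),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
            )
    return "\n".join(fasta_lines) + "\n", "\n".join(gtf_lines) + "\n"


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shared_kmer_fraction(a: str, b: str, k: int) -> float:
    """Jaccard fraction of shared k-mers between two sequences."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(len(a), len(b)):
        raise ValueError(f"k={k} exceeds shortest sequence length {min(len(a), len(b))}")
    ka, kb = _kmers(a, k), _kmers(b, k)
    return len(ka & kb) / len(ka | kb)


def pairwise_identity(
    a: TransgeneRecord, b: TransgeneRecord, k: int = DEFAULT_K
) -> IdentityResult:
    """Global-alignment percent identity between two transgene barcodes.

    Identity is matches / alignment length under the module's fixed scoring
    (the first optimal alignment, which Biopython returns deterministically).
    Positions involving ``N`` never count as matches. Also reports the shared
    k-mer fraction at ``k`` (clamped to the shortest sequence).
    """
    if not a.sequence or not b.sequence:
        raise RegistryError("cannot align empty sequences")
    alignment = _aligner().align(a.sequence, b.sequence)[0]
    sa, sb = alignment[0], alignment[1]
    length = len(sa)
    matches = sum(
        1 for x, y in zip(sa, sb) if x == y and x not in ("-", "N")
    )
    k_eff = min(k, len(a.sequence), len(b.sequence))
    return IdentityResult(
        pair=(a.name, b.name),
        percent_identity=100.0 * matches / length,
        aligned_length=length,
        shared_kmer_fraction=shared_kmer_fraction(a.sequence, b.sequence, k_eff),
        k=k_eff,
    )


def discriminability_report(
    registry: list[TransgeneRecord], k: int = DEFAULT_K
) -> pd.DataFrame:
    """All-pairs identity table with cross-alignment warning flags.

    A pair is flagged when any read-length k-mer is shared: a single shared
    k-mer means a read could align to either contig, so the two barcodes are
    not cleanly discriminable.
    """
    if len(registry) < 2:
        raise RegistryError("discriminability needs at least 2 transgenes")
    shortest = min(len(r) for r in registry)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest registry sequence ({shortest} nt)")
    rows = []
    for a, b in combinations(registry, 2):
        res = pairwise_identity(a, b, k=k)
        rows.append(
            {
                "name_a": a.name,
                "name_b": b.name,
                "percent_identity": res.percent_identity,
                "aligned_length": res.aligned_length,
                "shared_kmer_fraction": res.shared_kmer_fraction,
                "k": res.k,
                "warning": res.shared_kmer_fraction > 0.0,
            }
        )
    return pd.DataFrame(rows)
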