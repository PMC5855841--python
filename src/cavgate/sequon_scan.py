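"""N-glycosylation sequon (N-X-S/T, X != P) scanning and site conservation.

Identifies candidate N-linked glycosylation sites in protein sequences — the
motif that pins the single extracellular P-loop site N283 of the CaV2.1
alpha-1A subunit — and checks whether a given alignment column keeps both the
asparagine and an intact downstream sequon in each sequence.  Coordinates are
1-based residue indices, matching the N283-style numbering convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import InvalidInputError, SequenceParseError

__all__ = ["SequonHit", "find_sequons", "scan_fasta", "site_conservation", "hits_to_tsv"]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: X is tolerated on input as an unknown residue; it never completes a sequon.
INPUT_ALPHABET = AMINO_ACIDS | {"X"}
GAP_CHARS = set("-.")


@dataclass(frozen=True)
class SequonHit:
    """One N-X-S/T match: 1-based position of the N and the residue triplet."""

    position: int
    triplet: str
    sequence_id: str

    def __post_init__(self) -> None:
        if self.triplet[0] != "N" or self.triplet[1] == "P" or self.triplet[2] not in "ST":
            raise InvalidInputError(f"not a sequon: {self.triplet!r}")


def _check_alphabet(seq: str, sequence_id: str) -> str:
    seq = seq.upper()
    bad = set(seq) - INPUT_ALPHABET
    if bad:
        raise SequenceParseError(
            f"sequence {sequence_id!r} contains non-amino-acid characters: "
            f"{sorted(bad)}"
        )
    return seq


def find_sequons(seq: str, sequence_id: str = "") -> list[SequonHit]:
    """All (possibly overlapping) N-X-[S/T] motifs with X != P, ascending.

    ``X`` (unknown residue) is treated as a wildcard mismatch: it neither
    serves as the N nor as the S/T, and as the middle residue it cannot be
    ruled out as proline, so it does not complete a sequon either.
    """
    seq = _check_alphabet(seq, sequence_id)
    hits = []
    for i in range(len(seq) - 2):
        n, x, st = seq[i], seq[i + 1], seq[i + 2]
        if n == "N" and x not in ("P", "X") and st in ("S", "T"):
            hits.append(
                SequonHit(position=i + 1, triplet=seq[i : i + 3], sequence_id=sequence_id)
            )
    return hits


def scan_fasta(path: str) -> list[SequonHit]:
    """Scan every record of a FASTA file."""
    hits: list[SequonHit] = []
    for record in SeqIO.parse(path, "fasta"):
        hits.extend(find_sequons(str(record.seq), record.id))
    return hits


def site_conservation(
    alignment: Sequence[tuple[str, str]], column: int
) -> list[dict]:
    """Per-sequence sequon status at a 1-based alignment column.

    ``alignment`` is a list of ``(sequence_id, aligned_sequence)`` pairs of
    equal length.  For each sequence the flag is true iff the column holds an
    N and the next two ungapped residues complete the sequon (gaps are skipped
    when reading the +1/+2 context: the motif is a property of the ungapped
    sequence).
    """
    if not alignment:
        raise InvalidInputError("empty alignment")
    lengths = {len(seq) for _, seq in alignment}
    if len(lengths) != 1:
        raise InvalidInputError(f"ragged alignment: lengths {sorted(lengths)}")
    (length,) = lengths
    if not 1 <= column <= length:
        raise InvalidInputError(f"column {column} outside 1..{length}")

    rows = []
    for seq_id, aligned in alignment:
        seq = aligned.upper()
        _check_alphabet(seq.replace("-", "").replace(".", ""), seq_id)
        residue = seq[column - 1]
        context = [c for c in seq[column:] if c not in GAP_CHARS][:2]
        intact = (
            residue == "N"
            and len(context) == 2
            and context[0] not in ("P", "X")
            and context[1] in ("S", "T")
        )
        rows.append(
            {
                "sequence_id": seq_id,
                "residue": residue,
                "context": "".join(context),
                "sequon_intact": intact,
            }
        )
    return rows


def hits_to_tsv(hits: Iterable[SequonHit]) -> str:
    """Render hits as a TSV table (sequence_id, position, triplet)."""
    lines = ["sequence_id\tposition\ttriplet"]
    for hit in hits:
        lines.append(f"{hit.sequence_id}\t{hit.position}\t{hit.triplet}")
    return "\n".join(lines) + "\n"
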