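"""Transcript models: exon structure and CDS sequence in CDS coordinates.

All coordinates are 1-based, inclusive, in CDS space (HGVS ``c.``
convention, +1 = the A of the initiator ATG).  Exon junctions are reported
as the last CDS nucleotide of each non-terminal exon; the junction
nucleotide itself belongs to the upstream exon.  UTRs are ignored
throughout: the model covers the coding sequence only.
"""
from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import TranscriptLoadError, TranscriptValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
_VALID_NT = frozenset("ACGT")


@dataclass(frozen=True)
class TranscriptModel:
    """A single protein-coding transcript reduced to its CDS.

    Parameters
    ----------
    transcript_id : str
        Accession-like label.
    cds_sequence : str
        Sense-strand nucleotides from the A of the ATG through the natural
        stop codon inclusive.
    exon_cds_lengths : list of int
        CDS-overlapping length of each exon, 5' to 3'.  Exons contributing
        no coding sequence are omitted.
    """

    transcript_id: str
    cds_sequence: str
    exon_cds_lengths: list[int] = field(default_factory=list)

    def __post_init__(self):
        seq = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", seq)
        object.__setattr__(self, "exon_cds_lengths", list(self.exon_cds_lengths))
        if set(seq) - _VALID_NT:
            bad = sorted(set(seq) - _VALID_NT)
            raise TranscriptValidationError(f"non-ACGT characters in CDS: {bad}")
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise TranscriptValidationError(
                f"CDS length {len(seq)} is not a positive multiple of 3"
            )
        if seq[:3] != START_CODON:
            raise TranscriptValidationError(f"CDS does not begin with ATG: {seq[:3]}")
        if seq[-3:] not in STOP_CODONS:
            raise TranscriptValidationError(f"CDS does not end in a stop codon: {seq[-3:]}")
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in STOP_CODONS:
                raise TranscriptValidationError(
                    f"internal stop codon {seq[i:i + 3]} at codon {i // 3 + 1}"
                )
        lengths = self.exon_cds_lengths
        if not lengths or any(l <= 0 for l in lengths):
            raise TranscriptValidationError("exon CDS lengths must be positive")
        if sum(lengths) != len(seq):
            raise TranscriptValidationError(
                f"exon CDS lengths sum to {sum(lengths)}, CDS is {len(seq)} nt"
            )

    # -- derived structure -------------------------------------------------

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def n_codons(self) -> int:
        """Number of codons including the natural terminator."""
        return len(self.cds_sequence) // 3

    @property
    def exon_junctions_cds(self) -> list[int]:
        """Last CDS nucleotide of each non-terminal exon, ascending."""
        out, acc = [], 0
        for length in self.exon_cds_lengths[:-1]:
            acc += length
            out.append(acc)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "transcript_id": self.transcript_id,
            "cds_sequence": self.cds_sequence,
            "exon_cds_lengths": self.exon_cds_lengths,
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def last_junction_position(t: TranscriptModel) -> Optional[int]:
    """1-based CDS position of the last exon-exon junction, or None."""
    junctions = t.exon_junctions_cds
    return junctions[-1] if junctions else None


def exon_of_cds_position(t: TranscriptModel, p: int) -> tuple[int, int]:
    """Return (1-based exon index, that exon's CDS length) containing nt ``p``.

    Exon intervals are half-open on the partial sums, ``(prev, junction]``:
    the junction nucleotide belongs to the upstream exon.
    """
    if not 1 <= p <= t.cds_length:
        raise IndexError(f"CDS position {p} outside [1, {t.cds_length}]")
    idx = bisect_left(t.exon_junctions_cds, p)
    return idx + 1, t.exon_cds_lengths[idx]


# -- loaders ---------------------------------------------------------------


def load_transcript(
    source: str | Path,
    format: str = "json",
    fasta: str | Path | None = None,
    transcript_id: str | None = None,
) -> TranscriptModel:
    """Load a transcript model from JSON, GenBank, or GFF3+FASTA.

    ``format`` is one of ``json``, ``genbank``, ``gff3+fasta`` (the latter
    requires ``fasta``).  Minus-strand sources are reverse-complemented so
    ``cds_sequence`` is always sense strand, and all coordinates end up in
    1-based CDS space.
    """
    source = Path(source)
    if not source.exists():
        raise TranscriptLoadError(f"no such file: {source}")
    if format == "json":
        return _load_json(source)
    if format == "genbank":
        return _load_genbank(source)
    if format in ("gff3+fasta", "gff3"):
        if fasta is None:
            raise TranscriptLoadError("gff3+fasta format requires a FASTA path")
        return _load_gff3(source, Path(fasta), transcript_id)
    raise TranscriptLoadError(f"unknown transcript format: {format!r}")


def _load_json(path: Path) -> TranscriptModel:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise TranscriptLoadError(f"{path}: invalid JSON ({exc})") from exc
    missing = {"transcript_id", "cds_sequence", "exon_cds_lengths"} - set(payload)
    if missing:
        raise TranscriptLoadError(f"{path}: missing fields {sorted(missing)}")
    return TranscriptModel(
        transcript_id=payload["transcript_id"],
        cds_sequence=payload["cds_sequence"],
        exon_cds_lengths=list(payload["exon_cds_lengths"]),
    )


def _load_genbank(path: Path) -> TranscriptModel:
    from Bio import SeqIO

    record = SeqIO.read(str(path), "genbank")
    cds_features = [f for f in record.features if f.type == "CDS"]
    if len(cds_features) != 1:
        raise TranscriptLoadError(
            f"{record.id}: expected exactly one CDS feature, found {len(cds_features)}"
        )
    feature = cds_features[0]
    seq = str(feature.extract(record.seq)).upper()
    parts = sorted(feature.location.parts, key=lambda part: int(part.start))
    if feature.location.strand == -1:
        parts = parts[::-1]
    lengths = [len(part) for part in parts]
    return TranscriptModel(
        transcript_id=record.id, cds_sequence=seq, exon_cds_lengths=lengths
    )


def _load_gff3(gff_path: Path, fasta_path: Path, transcript_id: str | None) -> TranscriptModel:
    import gffutils
    from Bio import SeqIO

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_parent: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", ["?"])
        by_parent.setdefault(parents[0], []).append(feat)
    if not by_parent:
        raise TranscriptLoadError(f"{gff_path}: no CDS features")
    if transcript_id is not None:
        if transcript_id not in by_parent:
            raise TranscriptLoadError(
                f"{gff_path}: no CDS features with Parent={transcript_id!r}"
            )
        chosen = transcript_id
    elif len(by_parent) == 1:
        chosen = next(iter(by_parent))
    else:
        raise TranscriptLoadError(
            f"{gff_path}: multiple transcripts {sorted(by_parent)}; "
            "pass transcript_id to disambiguate"
        )
    feats = sorted(by_parent[chosen], key=lambda f: f.start)
    strands = {f.strand for f in feats}
    seqids = {f.seqid for f in feats}
    if len(strands) != 1 or len(seqids) != 1:
        raise TranscriptLoadError(f"{gff_path}: CDS features of {chosen} span strands/contigs")
    strand, seqid = strands.pop(), seqids.pop()
    genome = {rec.id: rec.seq for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if seqid not in genome:
        raise TranscriptLoadError(f"{fasta_path}: no sequence named {seqid!r}")
    # GFF3 coordinates are 1-based inclusive.
    pieces = [str(genome[seqid][f.start - 1 : f.end]).upper() for f in feats]
    lengths = [f.end - f.start + 1 for f in feats]
    seq = "".join(pieces)
    if strand == "-":
        from Bio.Seq import Seq

        seq = str(Seq(seq).reverse_complement())
        lengths = lengths[::-1]
    return TranscriptModel(
        transcript_id=chosen, cds_sequence=seq, exon_cds_lengths=lengths
    )
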