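"""cDNA HGVS parsing, sequence application, and PTC localization.

Supported coding edits: substitution, deletion, duplication, insertion and
delins, written against CDS coordinates (+1 = A of ATG).  Intronic or UTR
descriptions raise :class:`NotCodingEditError`; their transcript-level
consequence must be supplied as a :class:`TranscriptEdit` or as a protein
annotation instead.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import (
    HgvsParseError,
    NoTerminatorError,
    NotCodingEditError,
    ReferenceMismatchError,
    UnsupportedProteinHgvsError,
)
from .transcript import STOP_CODONS, TranscriptModel

_WS = re.compile(r"\s+")
_SUB = re.compile(r"^(\d+)([ACGT])>([ACGT])$")
_DELINS = re.compile(r"^(\d+)(?:_(\d+))?del([ACGT]*)ins([ACGT]+)$")
_DEL = re.compile(r"^(\d+)(?:_(\d+))?del([ACGT]*)$")
_DUP = re.compile(r"^(\d+)(?:_(\d+))?dup([ACGT]*)$")
_INS = re.compile(r"^(\d+)_(\d+)ins([ACGT]+)$")
_OFFSET = re.compile(r"\d+[+-]\d+|^[-*]")

VARIANT_KINDS = ("substitution", "deletion", "duplication", "insertion", "delins")


@dataclass(frozen=True)
class CdsVariant:
    """One structured cDNA-level edit.

    ``start``/``end`` are 1-based CDS positions.  For an insertion they are
    the flanking positions (``end == start + 1``); for a duplication they
    delimit the duplicated span, applied as an insertion of that span
    immediately after ``end``.
    """

    kind: str
    start: int
    end: int
    ref_allele: str = ""
    alt_allele: str = ""
    raw_hgvs: str = field(default="", compare=False)

    def __post_init__(self):
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}_{self.end}")
        if self.kind == "insertion" and (self.end != self.start + 1 or not self.alt_allele):
            raise ValueError("insertion requires end == start + 1 and a non-empty allele")
        for allele in (self.ref_allele, self.alt_allele):
            if set(allele) - set("ACGT"):
                raise ValueError(f"non-ACGT allele {allele!r}")

    @property
    def length_delta(self) -> int:
        """Net change in CDS length when the edit is applied."""
        span = self.end - self.start + 1
        if self.kind == "substitution":
            return 0
        if self.kind == "deletion":
            return -span
        if self.kind == "duplication":
            return span
        if self.kind == "insertion":
            return len(self.alt_allele)
        return len(self.alt_allele) - span  # delins


@dataclass(frozen=True)
class TranscriptEdit:
    """An arbitrary insertion into the CDS, e.g. a pseudo-exon inclusion.

    ``insert_position`` is the 1-based CDS nucleotide after which
    ``inserted_sequence`` is spliced in.
    """

    insert_position: int
    inserted_sequence: str

    def __post_init__(self):
        if not self.inserted_sequence:
            raise ValueError("inserted_sequence must be non-empty")
        if set(self.inserted_sequence) - set("ACGT"):
            raise ValueError("inserted_sequence must be A/C/G/T")
        if self.insert_position < 0:
            raise ValueError("insert_position must be >= 0")


@dataclass(frozen=True)
class PtcCall:
    """Location of a premature stop codon in the mutant reading frame.

    ``codon_index`` is the mutant-frame codon number (the canonical
    classification coordinate); ``cds_first_nt``/``cds_last_nt`` project
    the stop onto reference CDS coordinates by subtracting the net length
    inserted 5' of it.
    """

    codon_index: int
    cds_first_nt: int
    cds_last_nt: int
    protein_hgvs: Optional[str] = None
    is_natural_stop: bool = False

    def __post_init__(self):
        if self.codon_index < 1:
            raise ValueError("codon_index must be >= 1")
        if self.cds_last_nt != self.cds_first_nt + 2:
            raise ValueError("stop codon must span exactly 3 nt")


def parse_cdna_hgvs(s: str) -> CdsVariant:
    """Parse a cDNA HGVS string into a :class:`CdsVariant`.

    Internal whitespace is tolerated (tables often print ``c.380 T > A``).
    """
    body = _WS.sub("", s)
    if not body.startswith("c."):
        raise HgvsParseError(f"not a cDNA (c.) description: {s!r}", raw=s, position=0)
    body = body[2:]
    m = _SUB.match(body)
    if m:
        pos = int(m.group(1))
        return CdsVariant("substitution", pos, pos, m.group(2), m.group(3), s)
    m = _DELINS.match(body)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        ref = m.group(3)
        _check_span(s, start, end, ref)
        return CdsVariant("delins", start, end, ref, m.group(4), s)
    m = _DEL.match(body)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        ref = m.group(3)
        _check_span(s, start, end, ref)
        return CdsVariant("deletion", start, end, ref, "", s)
    m = _DUP.match(body)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        ref = m.group(3)
        _check_span(s, start, end, ref)
        return CdsVariant("duplication", start, end, ref, "", s)
    m = _INS.match(body)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise HgvsParseError(
                f"insertion flanks must be adjacent: {s!r}", raw=s
            )
        return CdsVariant("insertion", start, end, "", m.group(3), s)
    if _OFFSET.search(body):
        raise NotCodingEditError(
            f"{s!r} describes a non-coding position; supply the splice "
            "consequence as a TranscriptEdit or protein annotation"
        )
    raise HgvsParseError(f"unrecognized cDNA HGVS syntax: {s!r}", raw=s)


def _check_span(raw: str, start: int, end: int, stated: str) -> None:
    if end < start:
        raise HgvsParseError(f"end before start in {raw!r}", raw=raw)
    if stated and len(stated) != end - start + 1:
        raise HgvsParseError(
            f"stated allele {stated!r} does not fit span {start}_{end} in {raw!r}",
            raw=raw,
        )


def format_hgvs(v: CdsVariant) -> str:
    """Serialize a :class:`CdsVariant` back to a canonical c. string."""
    span = f"{v.start}" if v.start == v.end else f"{v.start}_{v.end}"
    if v.kind == "substitution":
        return f"c.{v.start}{v.ref_allele}>{v.alt_allele}"
    if v.kind == "deletion":
        return f"c.{span}del{v.ref_allele}"
    if v.kind == "duplication":
        return f"c.{span}dup{v.ref_allele}"
    if v.kind == "insertion":
        return f"c.{v.start}_{v.end}ins{v.alt_allele}"
    return f"c.{span}del{v.ref_allele}ins{v.alt_allele}"


def normalize_variant(v: CdsVariant, ref_cds: str) -> CdsVariant:
    """3'-shift an insertion and rename it a duplication where applicable.

    Used when *generating* HGVS names; parsed names are taken at face
    value.  Substitutions, deletions and delins are returned unchanged
    apart from filling in the reference allele.
    """
    if v.kind in ("substitution", "delins", "deletion", "duplication"):
        ref = ref_cds[v.start - 1 : v.end]
        return replace(v, ref_allele=ref if v.kind != "substitution" else ref)
    # insertion: shift 3' while the next reference base equals the first
    # inserted base (the resulting sequence is identical).
    pos, ins = v.start, v.alt_allele
    while pos < len(ref_cds) and ref_cds[pos] == ins[0]:
        ins = ins[1:] + ins[0]
        pos += 1
    n = len(ins)
    if pos >= n and ref_cds[pos - n : pos] == ins:
        return CdsVariant("duplication", pos - n + 1, pos, ins, "", v.raw_hgvs)
    return CdsVariant("insertion", pos, pos + 1, "", ins, v.raw_hgvs)


def apply_variant(
    t: TranscriptModel, v: Union[CdsVariant, TranscriptEdit]
) -> str:
    """Apply an edit to the reference CDS and return the mutant sequence."""
    seq = t.cds_sequence
    if isinstance(v, TranscriptEdit):
        if v.insert_position > len(seq):
            raise IndexError(
                f"insert position {v.insert_position} beyond CDS of {len(seq)} nt"
            )
        p = v.insert_position
        return seq[:p] + v.inserted_sequence + seq[p:]
    if v.end > len(seq):
        raise IndexError(f"variant span {v.start}_{v.end} beyond CDS of {len(seq)} nt")
    if v.ref_allele and v.kind in ("substitution", "deletion", "duplication", "delins"):
        found = seq[v.start - 1 : v.end]
        if found != v.ref_allele:
            raise ReferenceMismatchError(v.start, v.ref_allele, found)
    if v.kind == "substitution":
        return seq[: v.start - 1] + v.alt_allele + seq[v.start :]
    if v.kind == "deletion":
        return seq[: v.start - 1] + seq[v.end :]
    if v.kind == "duplication":
        dup = seq[v.start - 1 : v.end]
        return seq[: v.end] + dup + seq[v.end :]
    if v.kind == "insertion":
        return seq[: v.start] + v.alt_allele + seq[v.start :]
    return seq[: v.start - 1] + v.alt_allele + seq[v.end :]  # delins


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def find_ptc(t: TranscriptModel, mutant_cds: str) -> Optional[PtcCall]:
    """Locate the first stop codon of the mutant reading frame.

    Returns None when that stop is the natural terminator, i.e. its mutant
    codon index maps back — after adjusting for upstream length changes —
    to the reference CDS's final codon.  Raises
    :class:`NoTerminatorError` when the frame contains no stop at all.
    """
    ref = t.cds_sequence
    if not mutant_cds.startswith("ATG"):
        raise ValueError("mutant CDS must begin with ATG")
    prefix = _common_prefix_len(ref, mutant_cds)
    net = len(mutant_cds) - len(ref)
    ref_stop_codon = len(ref) // 3
    for i in range(1, len(mutant_cds) // 3 + 1):
        codon = mutant_cds[3 * i - 3 : 3 * i]
        if codon not in STOP_CODONS:
            continue
        first_mut = 3 * i - 2
        shift = net if first_mut > prefix else 0
        first_ref = first_mut - shift
        if shift % 3 == 0 and (first_ref + 2) // 3 == ref_stop_codon:
            return None
        call = PtcCall(
            codon_index=i,
            cds_first_nt=first_ref,
            cds_last_nt=first_ref + 2,
        )
        return replace(call, protein_hgvs=protein_hgvs_of(ref, mutant_cds, call))
    raise NoTerminatorError(
        "no stop codon in mutant reading frame (stop-loss; not classifiable)"
    )


def protein_hgvs_of(ref_cds: str, mutant_cds: str, ptc: PtcCall) -> str:
    """Protein-level name of a PTC from the two sequences.

    First residue differing from the reference (left to right) anchors the
    name: ``p.Xaa{pos}*`` when that residue is the stop itself, otherwise
    ``p.Xaa{pos}Yaafs*{N}`` with ``N = ptc.codon_index - pos + 1``.
    """
    ref_prot = str(Seq(ref_cds).translate())
    mut_len = len(mutant_cds) - len(mutant_cds) % 3
    mut_prot = str(Seq(mutant_cds[:mut_len]).translate())
    pos = None
    for j, (a, b) in enumerate(zip(ref_prot, mut_prot), start=1):
        if a != b:
            pos = j
            break
    if pos is None or pos > ptc.codon_index:
        raise ValueError("sequences do not diverge before the PTC")
    ref_aa = seq3(ref_prot[pos - 1])
    if mut_prot[pos - 1] == "*":
        return f"p.{ref_aa}{pos}*"
    new_aa = seq3(mut_prot[pos - 1])
    n = ptc.codon_index - pos + 1
    return f"p.{ref_aa}{pos}{new_aa}fs*{n}"


_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|Tyr|Val"
)
_AA = f"(?:{_AA3}|[{_AA1}])"
_P_NONSENSE = re.compile(rf"^p\.{_AA}(\d+)(?:\*|Ter)$")
_P_FRAMESHIFT = re.compile(rf"^p\.{_AA}(\d+){_AA}fs\*(\d+)$")


def ptc_codon_from_protein_hgvs(s: str) -> int:
    """PTC codon index implied by a nonsense or frameshift protein name.

    Nonsense ``p.Xaa{pos}*`` maps to ``pos``; frameshift
    ``p.Xaa{pos}Yaafs*{N}`` maps to ``pos + N - 1``.  Three-letter and
    one-letter amino-acid codes are both accepted.
    """
    body = _WS.sub("", s).replace("(", "").replace(")", "")
    m = _P_NONSENSE.match(body)
    if m:
        return int(m.group(1))
    m = _P_FRAMESHIFT.match(body)
    if m:
        return int(m.group(1)) + int(m.group(2)) - 1
    raise UnsupportedProteinHgvsError(
        f"{s!r} is not a supported nonsense/frameshift protein description"
    )
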