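"""Coding-indel consequences and frameshift nomenclature.

Applies HGVS-style ``c.`` indels (1-based, inclusive deletion spans) to a
coding sequence, translates the result, and derives/interprets ``p.`` style
frameshift descriptions of the form ``p.<ref><pos><alt>fsX<k>``: the first
affected residue (anchor) followed by the offset ``k`` locating the premature
stop in the shifted reading frame. With a retained anchor (ref aa equals alt
aa, e.g. ``p.L471LfsX56``) the stop sits at position ``pos + k`` — here 527;
with a substituted anchor (``p.L3SfsX2``) at ``pos + k − 1``. Single-letter
amino-acid codes with ``X`` for the termination codon are used throughout.

Bracketed complex alleles such as ``c.[80_83del4;79_84ins22]`` (a deletion
plus an insertion described against overlapping coordinates) are normalised
to a single replacement span: the deleted range is replaced by the inserted
sequence. Insertions stated only by length (``ins22``) parse into a variant
usable for reading-frame arithmetic but cannot be applied to a sequence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import (
    CoordinateError,
    NomenclatureError,
    NotAFrameshiftError,
    SequenceError,
)

_NUC = set("ACGT")

SYNONYMOUS = "synonymous-frame"
MISSENSE = "missense-set"
FRAMESHIFT = "frameshift"
STOP_LOSS = "stop-loss"


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS: starts ATG, ends in a stop, length a multiple of 3."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence
        if set(seq) - _NUC:
            raise SequenceError(f"{self.id}: non-ACGT symbols {set(seq) - _NUC}")
        if len(seq) % 3 != 0:
            raise SequenceError(f"{self.id}: length {len(seq)} not a multiple of 3")
        if not seq.startswith("ATG"):
            raise SequenceError(f"{self.id}: CDS must start with ATG")
        if seq[-3:] not in ("TAA", "TAG", "TGA"):
            raise SequenceError(f"{self.id}: CDS must end with a stop codon")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodingVariant:
    """A deletion span plus insertion in 1-based inclusive c. coordinates.

    A pure insertion between bases k and k+1 is encoded as
    ``del_start = k + 1, del_end = k`` (empty span). ``inserted`` is ``None``
    when only the insertion length is known.
    """

    del_start: int
    del_end: int
    inserted: str | None = ""
    ins_length: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if self.del_end < self.del_start - 1:
            raise CoordinateError(
                f"invalid deletion span {self.del_start}_{self.del_end}"
            )
        if self.inserted is not None:
            if set(self.inserted) - _NUC:
                raise SequenceError(f"insertion has non-ACGT symbols: {self.inserted}")
            object.__setattr__(self, "ins_length", len(self.inserted))
        if self.deletion_length == 0 and self.ins_length == 0:
            raise CoordinateError("variant deletes and inserts nothing")

    @property
    def deletion_length(self) -> int:
        return max(0, self.del_end - self.del_start + 1)

    @property
    def net_length_change(self) -> int:
        return self.ins_length - self.deletion_length

    @property
    def shifts_frame(self) -> bool:
        return self.net_length_change % 3 != 0


# ---------------------------------------------------------------------------
# HGVS-like c. descriptor parsing
# ---------------------------------------------------------------------------

_DEL_RE = re.compile(r"^(\d+)(?:_(\d+))?del([ACGT]+|\d+)?$")
_INS_RE = re.compile(r"^(\d+)_(\d+)ins([ACGT]+|\d+)$")
_DELINS_RE = re.compile(r"^(\d+)(?:_(\d+))?delins([ACGT]+|\d+)$")


def _strip_prefix(text: str) -> str:
    text = text.strip()
    if text.startswith("c."):
        text = text[2:]
    return text


def parse_coding_variant(text: str) -> CodingVariant:
    """Parse a ``c.`` descriptor: del / ins / delins / bracketed [del;ins]."""
    body = _strip_prefix(text)
    if body.startswith("[") and body.endswith("]"):
        return _parse_bracket_allele(body[1:-1], text)
    m = _DELINS_RE.match(body)
    if m:
        start, end = int(m.group(1)), int(m.group(2) or m.group(1))
        return CodingVariant(start, end, **_ins_payload(m.group(3)))
    m = _DEL_RE.match(body)
    if m:
        start, end = int(m.group(1)), int(m.group(2) or m.group(1))
        stated = m.group(3)
        if stated and stated.isdigit() and int(stated) != end - start + 1:
            raise NomenclatureError(
                f"{text}: stated deletion length {stated} != span {end - start + 1}"
            )
        return CodingVariant(start, end, inserted="")
    m = _INS_RE.match(body)
    if m:
        left, right = int(m.group(1)), int(m.group(2))
        if right != left + 1:
            raise NomenclatureError(
                f"{text}: insertion positions must be adjacent ({left}_{right})"
            )
        return CodingVariant(left + 1, left, **_ins_payload(m.group(3)))
    raise NomenclatureError(f"unparseable variant descriptor: {text!r}")


def _ins_payload(spec: str) -> dict:
    if spec.isdigit():
        return {"inserted": None, "ins_length": int(spec)}
    return {"inserted": spec}


def _parse_bracket_allele(body: str, original: str) -> CodingVariant:
    """Normalise ``[<del>;<ins>]`` into one replacement over the deleted span."""
    parts = [p.strip() for p in body.split(";")]
    del_part = ins_part = None
    for p in parts:
        if "ins" in p and "del" not in p:
            ins_part = p
        elif "del" in p:
            del_part = p
        else:
            raise NomenclatureError(f"{original}: unsupported allele component {p!r}")
    if del_part is None or ins_part is None:
        raise NomenclatureError(f"{original}: bracket allele needs a del and an ins part")
    dm = _DEL_RE.match(del_part)
    if not dm:
        raise NomenclatureError(f"{original}: bad deletion component {del_part!r}")
    start, end = int(dm.group(1)), int(dm.group(2) or dm.group(1))
    im = re.match(r"^(\d+)_(\d+)ins([ACGT]+|\d+)$", ins_part)
    if not im:
        raise NomenclatureError(f"{original}: bad insertion component {ins_part!r}")
    payload = _ins_payload(im.group(3))
    return CodingVariant(
        start, end,
        note=f"normalised from {original}: replacement of span "
             f"{start}_{end} by the {payload.get('ins_length') or len(payload['inserted'])}-nt insertion",
        **payload,
    )


# ---------------------------------------------------------------------------
# Applying and translating
# ---------------------------------------------------------------------------

def apply_indel(cds: CodingSequence | str, variant: CodingVariant) -> str:
    """Return the mutant nucleotide string after deletion + insertion."""
    seq = cds.sequence if isinstance(cds, CodingSequence) else str(cds)
    if variant.inserted is None:
        raise SequenceError(
            "insertion bases unknown (length-only descriptor); cannot apply"
        )
    n = len(seq)
    if variant.deletion_length > 0:
        if not (1 <= variant.del_start <= variant.del_end <= n):
            raise CoordinateError(
                f"deletion {variant.del_start}_{variant.del_end} outside CDS of length {n}"
            )
    elif not (0 <= variant.del_end <= n):
        raise CoordinateError(f"insertion point {variant.del_end} outside CDS")
    return seq[: variant.del_start - 1] + variant.inserted + seq[variant.del_end:]


def translate_to_stop(nt: str) -> tuple[str, bool]:
    """Translate from position 1 to the first stop; returns (protein, stop_seen)."""
    if set(nt) - _NUC:
        raise SequenceError(f"non-ACGT symbols: {sorted(set(nt) - _NUC)}")
    if len(nt) < 3:
        raise SequenceError("need at least one codon")
    full = str(Seq(nt[: len(nt) // 3 * 3]).translate())
    stop = full.find("*")
    if stop == -1:
        return full, False
    return full[:stop], True


# ---------------------------------------------------------------------------
# Protein-level description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinConsequence:
    kind: str
    ref_aa: str | None = None
    position: int | None = None
    alt_aa: str | None = None
    ter_offset: int | None = None
    stop_position: int | None = None
    notation: str | None = None


def describe_frameshift(
    ref_protein: str, alt_protein: str, alt_has_stop: bool = True
) -> ProteinConsequence:
    """Describe the divergence of a frameshifted protein from its reference.

    The anchor is the first residue at which the two translations diverge
    (the stop codon counts as residue ``X``); the Ter offset ``k`` is chosen
    so the premature stop sits at ``anchor + k − 1`` (substituted-anchor
    convention, the form this function emits).
    """
    ref_ext = ref_protein + "X"
    alt_ext = alt_protein + ("X" if alt_has_stop else "")
    i = 0
    limit = min(len(ref_ext), len(alt_ext))
    while i < limit and ref_ext[i] == alt_ext[i]:
        i += 1
    if i >= len(alt_ext) and alt_has_stop:
        raise NotAFrameshiftError("translations are identical; nothing to describe")
    if i >= len(alt_ext):  # alt ran out without a stop: stop-loss, no divergence
        raise NotAFrameshiftError("no divergence before the truncated end")
    pos = i + 1
    ref_aa = ref_ext[i] if i < len(ref_ext) else "X"
    alt_aa = alt_ext[i]
    if not alt_has_stop:
        return ProteinConsequence(
            kind=STOP_LOSS, ref_aa=ref_aa, position=pos, alt_aa=alt_aa,
            notation=f"p.{ref_aa}{pos}{alt_aa}fs",
        )
    stop_position = len(alt_protein) + 1
    ter_offset = stop_position - pos + 1
    return ProteinConsequence(
        kind=FRAMESHIFT,
        ref_aa=ref_aa,
        position=pos,
        alt_aa=alt_aa,
        ter_offset=ter_offset,
        stop_position=stop_position,
        notation=f"p.{ref_aa}{pos}{alt_aa}fsX{ter_offset}",
    )


def classify_indel(cds: CodingSequence, variant: CodingVariant) -> ProteinConsequence:
    """Full consequence call from a CDS and a variant."""
    if not variant.shifts_frame:
        if variant.inserted is None:
            return ProteinConsequence(kind=MISSENSE)
        ref, _ = translate_to_stop(cds.sequence)
        alt, _ = translate_to_stop(apply_indel(cds, variant))
        return ProteinConsequence(kind=SYNONYMOUS if ref == alt else MISSENSE)
    if variant.inserted is None:
        return ProteinConsequence(kind=FRAMESHIFT)
    ref, _ = translate_to_stop(cds.sequence)
    alt, alt_stop = translate_to_stop(apply_indel(cds, variant))
    return describe_frameshift(ref, alt, alt_has_stop=alt_stop)


_FS_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])fsX(\d+)$")


def stop_position_from_fs(nomenclature: str) -> int:
    """Absolute residue position of the premature stop encoded in a fsX string.

    Retained anchor (ref aa == alt aa, e.g. ``p.L471LfsX56``): position + k.
    Substituted anchor (``p.L3SfsX2``): position + k − 1. Published usage is
    not always consistent for substituted anchors, so those emit a warning.
    """
    m = _FS_RE.match(nomenclature.strip())
    if not m:
        raise NomenclatureError(f"malformed frameshift nomenclature: {nomenclature!r}")
    ref_aa, pos, alt_aa, k = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
    if ref_aa == alt_aa:
        return pos + k
    warnings.warn(
        f"{nomenclature}: substituted-anchor fsX counting conventions differ in "
        "the literature; using stop = position + offset - 1",
        stacklevel=2,
    )
    return pos + k - 1
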