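"""Read and write UniProtKB/Swiss-Prot flat-file (DAT) records.

The flat file is a record-oriented text format in which each line starts
with a two-letter code (ID, AC, DE, OC, OX, KW, CC, DR, PE, FT, SQ) and
each entry is terminated by a ``//`` line.  This module maps records onto
a small dataclass model carrying exactly the fields the downstream venom
analysis needs: identifiers, taxonomy pointers, keywords, the TISSUE
SPECIFICITY / SIMILARITY / TOXIC DOSE comment blocks, GO cross-references,
the protein-existence (PE) evidence level, the sequence, and the feature
table.

Two feature-table dialects exist in archived releases.  The canonical
dialect here is the modern single-line syntax (``FT   SIGNAL   1..22``);
the legacy column-based dialect (pre-2019 releases) is accepted on read
via ``legacy_ft=True`` but never written, so that
``read_dat(write_dat(d)) == d`` holds exactly.

Endpoint qualifiers ``?``, ``?N``, ``<N`` and ``>N`` mark a residue
position as not reliably known; they clear the corresponding
``start_known``/``end_known`` flag on the :class:`Feature`.
"""
from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import IO, Iterable, NamedTuple, Optional, Union

log = logging.getLogger(__name__)

__all__ = [
    "FeatureKind",
    "Feature",
    "GoRef",
    "ProteinEntry",
    "Dataset",
    "ParseError",
    "ValidationError",
    "read_dat",
    "write_dat",
    "extract_family_raw",
]


class ParseError(ValueError):
    """A flat-file record is structurally malformed."""


class ValidationError(ValueError):
    """A parsed record violates a model invariant."""


class FeatureKind(str, Enum):
    SIGNAL = "SIGNAL"
    PROPEP = "PROPEP"
    CHAIN = "CHAIN"
    PEPTIDE = "PEPTIDE"
    DISULFID = "DISULFID"
    CARBOHYD = "CARBOHYD"
    MOD_RES = "MOD_RES"
    CROSSLNK = "CROSSLNK"
    LIPID = "LIPID"
    OTHER = "OTHER"

    @classmethod
    def from_key(cls, key: str) -> "FeatureKind":
        try:
            return cls(key)
        except ValueError:
            return cls.OTHER


#: Feature kinds whose incomplete endpoints make an entry a fragment and
#: which define processed-subsequence ranges (signal peptide, propeptide,
#: mature chain, released peptide).
STRUCTURAL_KINDS = frozenset(
    {FeatureKind.SIGNAL, FeatureKind.PROPEP, FeatureKind.CHAIN, FeatureKind.PEPTIDE}
)


@dataclass(frozen=True)
class Feature:
    """One positional annotation from the FT block.

    ``start``/``end`` are 1-based inclusive residue indices; ``None``
    means the position is entirely unstated (bare ``?``).  A position may
    carry a value yet still be unreliable (``<N``, ``>N``, ``?N``), in
    which case the ``*_known`` flag is False.
    """

    kind: FeatureKind
    start: Optional[int]
    end: Optional[int]
    start_known: bool = True
    end_known: bool = True
    description: str = ""
    #: original FT key for kinds collapsed to OTHER (round-trip support)
    raw_key: str = ""

    def __post_init__(self) -> None:
        if self.start is None and self.start_known:
            object.__setattr__(self, "start_known", False)
        if self.end is None and self.end_known:
            object.__setattr__(self, "end_known", False)
        if (
            self.start_known
            and self.end_known
            and self.start is not None
            and self.end is not None
            and self.start > self.end
        ):
            raise ValidationError(
                f"feature {self.kind.value}: start {self.start} > end {self.end}"
            )

    @property
    def fully_known(self) -> bool:
        return self.start_known and self.end_known


class GoRef(NamedTuple):
    """One GO cross-reference: identifier, aspect (F/P/C) and term label."""

    go_id: str
    aspect: str
    label: str


@dataclass
class ProteinEntry:
    """One Swiss-Prot record in the pipeline's model."""

    accession: str
    entry_name: str
    sequence: str
    protein_name: str = ""
    is_fragment: bool = False
    taxid: int = 0
    lineage_text: tuple = ()
    keywords: frozenset = frozenset()
    tissue_specificity: Optional[str] = None
    family_raw: Optional[str] = None
    toxic_dose_texts: tuple = ()
    go_refs: tuple = ()
    evidence_level: int = 5
    snapshot_year: int = 0
    features: tuple = ()
    #: comment blocks other than the three modeled topics, kept opaque
    other_comments: tuple = ()

    def __post_init__(self) -> None:
        self.lineage_text = tuple(self.lineage_text)
        self.keywords = frozenset(self.keywords)
        self.toxic_dose_texts = tuple(self.toxic_dose_texts)
        self.go_refs = tuple(GoRef(*g) for g in self.go_refs)
        self.features = tuple(self.features)
        self.other_comments = tuple(tuple(c) for c in self.other_comments)

    def validate(self) -> None:
        if not self.accession:
            raise ValidationError("entry with empty accession")
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        if self.evidence_level not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"{self.accession}: evidence level {self.evidence_level} outside 1-5"
            )
        n = len(self.sequence)
        for ft in self.features:
            for pos, known in ((ft.start, ft.start_known), (ft.end, ft.end_known)):
                if known and pos is not None and not (1 <= pos <= n):
                    raise ValidationError(
                        f"{self.accession}: feature {ft.kind.value} position "
                        f"{pos} outside sequence of length {n}"
                    )


@dataclass
class Dataset:
    """A collection of entries from one release snapshot."""

    year: int = 0
    entries: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def validate(self) -> None:
        seen = set()
        for e in self.entries:
            e.validate()
            if e.accession in seen:
                raise ValidationError(f"duplicate accession {e.accession}")
            seen.add(e.accession)


# ---------------------------------------------------------------------------
# reading

_FAMILY_RE = re.compile(r"Belongs to the (.+?)\.?\s*$")
_GO_RE = re.compile(r"GO;\s*(GO:\d+);\s*([FPC]):([^;]+);")

_PE_LABELS = {
    1: "Evidence at protein level",
    2: "Evidence at transcript level",
    3: "Inferred from homology",
    4: "Predicted",
    5: "Uncertain",
}


def _parse_pos(tok: str):
    """Parse one FT position token -> (value, known)."""
    tok = tok.strip()
    if tok == "?":
        return None, False
    if tok[0] in "<>?":
        return int(tok[1:]), False
    return int(tok), True


def _split_records(lines: list) -> Iterable[list]:
    chunk: list = []
    for lineno, line in enumerate(lines, 1):
        if line.rstrip() == "//":
            yield chunk
            chunk = []
        else:
            chunk.append((lineno, line.rstrip("\n")))
    trailing = [ln for _, ln in chunk if ln.strip()]
    if trailing:
        raise ParseError(
            f"record starting at {trailing[0]!r} is missing its '//' terminator"
        )


def _parse_ft_modern(ft_lines: list) -> list:
    feats: list = []
    pending_note: Optional[list] = None
    for lineno, line in ft_lines:
        body = line[5:]
        if body[:1].isspace() or body.startswith("/"):
            # continuation line
            text = body.strip()
            if not feats:
                raise ParseError(f"line {lineno}: FT continuation before any feature")
            if text.startswith("/note="):
                pending_note = [text[len("/note=") :]]
            elif pending_note is not None:
                pending_note.append(text)
            else:
                continue  # qualifier other than /note: ignored
            joined = " ".join(pending_note)
            if joined.endswith('"') and len(joined) > 1:
                desc = joined.strip('"')
                last = feats[-1]
                feats[-1] = replace(last, description=desc)
                pending_note = None
        else:
            parts = body.split()
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: malformed FT line {line!r}")
            key, loc = parts
            if ".." in loc:
                a, b = loc.split("..", 1)
                start, s_known = _parse_pos(a)
                end, e_known = _parse_pos(b)
            else:
                start, s_known = _parse_pos(loc)
                end, e_known = start, s_known
            kind = FeatureKind.from_key(key)
            feats.append(
                Feature(
                    kind=kind,
                    start=start,
                    end=end,
                    start_known=s_known,
                    end_known=e_known,
                    raw_key=key if kind is FeatureKind.OTHER else "",
                )
            )
    return feats


def _parse_ft_legacy(ft_lines: list) -> list:
    """Legacy column-based FT dialect (accepted on read only)."""
    feats: list = []
    for lineno, line in ft_lines:
        body = line[5:]
        if body[:1].isspace():
            if not feats:
                raise ParseError(f"line {lineno}: FT continuation before any feature")
            last = feats[-1]
            extra = body.strip().rstrip(".")
            desc = (last.description + " " + extra).strip()
            feats[-1] = replace(last, description=desc)
            continue
        parts = body.split(None, 3)
        if len(parts) < 3:
            raise ParseError(f"line {lineno}: malformed legacy FT line {line!r}")
        key, a, b = parts[0], parts[1], parts[2]
        desc = parts[3].strip().rstrip(".") if len(parts) == 4 else ""
        start, s_known = _parse_pos(a)
        end, e_known = _parse_pos(b)
        kind = FeatureKind.from_key(key)
        feats.append(
            Feature(
                kind=kind,
                start=start,
                end=end,
                start_known=s_known,
                end_known=e_known,
                description=desc,
                raw_key=key if kind is FeatureKind.OTHER else "",
            )
        )
    return feats


def _parse_entry(chunk: list, year: int, legacy_ft: bool) -> ProteinEntry:
    entry_name = None
    accession = None
    protein_name = ""
    is_fragment = False
    taxid = 0
    lineage: list = []
    keywords: list = []
    cc_blocks: list = []  # (topic, text)
    go_refs: list = []
    evidence = 5
    seq_parts: list = []
    in_sq = False
    sq_seen = False
    ft_lines: list = []

    for lineno, line in chunk:
        code = line[:2]
        if in_sq and code == "  ":
            seq_parts.append(line.replace(" ", ""))
            continue
        in_sq = False
        body = line[5:] if len(line) > 5 else ""
        if code == "ID":
            entry_name = body.split()[0] if body.split() else None
        elif code == "AC":
            if accession is None:
                first = body.split(";")[0].strip()
                if first:
                    accession = first
        elif code == "DE":
            stripped = body.strip()
            if stripped.startswith("RecName: Full="):
                if not protein_name:
                    protein_name = stripped[len("RecName: Full=") :].rstrip(";")
            elif stripped.startswith("Flags:") and "Fragment" in stripped:
                is_fragment = True
        elif code == "OC":
            for name in body.split(";"):
                name = name.strip().rstrip(".")
                if name:
                    lineage.append(name)
        elif code == "OX":
            m = re.search(r"NCBI_TaxID=(\d+)", body)
            if m:
                taxid = int(m.group(1))
        elif code == "KW":
            for kw in body.split(";"):
                kw = kw.strip().rstrip(".")
                if kw:
                    keywords.append(kw)
        elif code == "CC":
            stripped = body.strip()
            if stripped.startswith("-!-"):
                rest = stripped[3:].strip()
                if ":" in rest:
                    topic, text = rest.split(":", 1)
                    cc_blocks.append([topic.strip(), text.strip()])
                else:
                    cc_blocks.append([rest, ""])
            elif cc_blocks:
                cc_blocks[-1][1] = (cc_blocks[-1][1] + " " + stripped).strip()
        elif code == "DR":
            m = _GO_RE.search(body)
            if m:
                go_refs.append(GoRef(m.group(1), m.group(2), m.group(3).strip()))
        elif code == "PE":
            m = re.match(r"(\d)", body.strip())
            if m:
                evidence = int(m.group(1))
        elif code == "FT":
            ft_lines.append((lineno, line))
        elif code == "SQ":
            sq_seen = True
            in_sq = True

    first_line = chunk[0][1] if chunk else "<empty record>"
    if entry_name is None:
        raise ParseError(f"record starting at {first_line!r}: missing ID line")
    if accession is None:
        raise ParseError(f"record starting at {first_line!r}: missing AC line")
    if not sq_seen:
        raise ParseError(f"record starting at {first_line!r}: missing SQ line")

    tissue = None
    family_raw = None
    doses: list = []
    other: list = []
    for topic, text in cc_blocks:
        if topic == "TISSUE SPECIFICITY":
            if tissue is None:
                tissue = text
            else:
                other.append((topic, text))
        elif topic == "TOXIC DOSE":
            doses.append(text)
        elif topic == "SIMILARITY":
            m = _FAMILY_RE.search(text)
            if m:
                if family_raw is None:
                    family_raw = m.group(1)
                else:
                    log.warning(
                        "%s: multiple SIMILARITY family statements; keeping the first",
                        accession,
                    )
            else:
                other.append((topic, text))
        else:
            other.append((topic, text))

    features = (
        _parse_ft_legacy(ft_lines) if legacy_ft else _parse_ft_modern(ft_lines)
    )

    entry = ProteinEntry(
        accession=accession,
        entry_name=entry_name,
        sequence="".join(seq_parts),
        protein_name=protein_name,
        is_fragment=is_fragment,
        taxid=taxid,
        lineage_text=tuple(lineage),
        keywords=frozenset(keywords),
        tissue_specificity=tissue,
        family_raw=family_raw,
        toxic_dose_texts=tuple(doses),
        go_refs=tuple(go_refs),
        evidence_level=evidence,
        snapshot_year=year,
        features=tuple(features),
        other_comments=tuple(other),
    )
    entry.validate()
    return entry


def read_dat(
    stream: Union[str, IO[str]], year: int = 0, legacy_ft: bool = False
) -> Dataset:
    """Parse one or more flat-file entries into a :class:`Dataset`.

    Parameters
    ----------
    stream:
        Flat-file text, or a text file object.  Each entry must end with
        a ``//`` line.
    year:
        Snapshot year recorded on the dataset and every entry.
    legacy_ft:
        Accept the legacy column-based feature-table dialect instead of
        the modern ``start..end`` syntax.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream
    lines = text.splitlines()
    entries = []
    for chunk in _split_records(lines):
        if not any(ln.strip() for _, ln in chunk):
            raise ParseError("empty record before '//' terminator")
        entries.append(_parse_entry(chunk, year, legacy_ft))
    ds = Dataset(year=year, entries=entries)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# writing


def _fmt_pos(value: Optional[int], known: bool) -> str:
    if value is None:
        return "?"
    return str(value) if known else f"?{value}"


def _write_entry(e: ProteinEntry, out: io.StringIO) -> None:
    n = len(e.sequence)
    out.write(f"ID   {e.entry_name:<24}Reviewed;{n:>12} AA.\n")
    out.write(f"AC   {e.accession};\n")
    if e.protein_name:
        out.write(f"DE   RecName: Full={e.protein_name};\n")
    if e.is_fragment:
        out.write("DE   Flags: Fragment;\n")
    if e.lineage_text:
        out.write("OS   Synthetic organism.\n")
        out.write("OC   " + "; ".join(e.lineage_text) + ".\n")
    out.write(f"OX   NCBI_TaxID={e.taxid};\n")
    if e.keywords:
        out.write("KW   " + "; ".join(sorted(e.keywords)) + ".\n")
    if e.tissue_specificity is not None:
        out.write(f"CC   -!- TISSUE SPECIFICITY: {e.tissue_specificity}\n")
    for text in e.toxic_dose_texts:
        out.write(f"CC   -!- TOXIC DOSE: {text}\n")
    if e.family_raw is not None:
        out.write(f"CC   -!- SIMILARITY: Belongs to the {e.family_raw}.\n")
    for topic, text in e.other_comments:
        out.write(f"CC   -!- {topic}: {text}\n")
    for ref in e.go_refs:
        out.write(f"DR   GO; {ref.go_id}; {ref.aspect}:{ref.label}; IEA:Synthetic.\n")
    out.write(f"PE   {e.evidence_level}: {_PE_LABELS[e.evidence_level]};\n")
    for ft in e.features:
        key = ft.raw_key or ft.kind.value
        if (
            ft.start == ft.end
            and ft.start is not None
            and ft.start_known
            and ft.end_known
        ):
            loc = str(ft.start)
        else:
            loc = f"{_fmt_pos(ft.start, ft.start_known)}..{_fmt_pos(ft.end, ft.end_known)}"
        out.write(f"FT   {key:<16}{loc}\n")
        if ft.description:
            out.write(f'FT                   /note="{ft.description}"\n')
    out.write(f"SQ   SEQUENCE   {n} AA;  0 MW;  0000000000000000 CRC64;\n")
    for i in range(0, n, 60):
        block = e.sequence[i : i + 60]
        groups = " ".join(block[j : j + 10] for j in range(0, len(block), 10))
        out.write(f"     {groups}\n")
    out.write("//\n")


def write_dat(dataset: Dataset) -> str:
    """Serialize a dataset to canonical flat-file text.

    The output uses the modern feature-table dialect and single-line
    comment blocks so that ``read_dat(write_dat(d))`` reproduces every
    modeled field exactly.  Invalid datasets are refused.
    """
    dataset.validate()
    out = io.StringIO()
    for e in dataset.entries:
        _write_entry(e, out)
    return out.getvalue()


def extract_family_raw(entry: ProteinEntry) -> Optional[str]:
    """Protein-family clause from the SIMILARITY comment, if present.

    Returns the text following "Belongs to the" with the trailing period
    removed; ``None`` marks the entry "Unassigned" downstream.
    """
    return entry.family_raw
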