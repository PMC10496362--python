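"""Streaming parsers for the three source XML dialects.

Each reader turns one XML dialect into a uniform stream of
:class:`SourceRecord` values:

* UniProtKB entry XML — ``<entry>`` elements carrying ``<accession>``,
  ``<recommendedName>``, ``<alternativeName>``, gene ``<name type="primary">``
  / ``<name type="synonym">``, the NCBI-Taxonomy ``<dbReference>`` and GeneID
  cross-references.
* BioGRID PSI-MI 2.5 interactor XML — ``<interactor>`` elements carrying
  ``<shortLabel>``, ``<alias>``, the ``ncbiTaxId`` organism attribute and
  ``<xref>`` entries.
* NCBI Entrezgene XML — ``<Entrezgene>`` elements carrying ``<GeneID>``,
  ``<Symbol>``, a ``;``-separated ``<Synonyms>`` field, ``<TaxID>`` and
  ``<dbXrefs>``.

Parsing is incremental (``lxml.etree.iterparse``): memory is bounded per
record, not per file, so multi-gigabyte dumps can be processed.  Only the
name/taxonomy/cross-reference element subset above is interpreted; unknown
elements are ignored rather than rejected, since real dumps carry far more
tags than this pipeline uses.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "XRef",
    "TaggedValue",
    "SourceRecord",
    "ParseError",
    "parse_uniprot",
    "parse_biogrid",
    "parse_ncbigene",
    "extract_tag_value",
    "open_xml",
]


class Source(str, Enum):
    """The three synonym databases integrated by the pipeline."""

    UNIPROT = "uniprot"
    BIOGRID = "biogrid"
    NCBIGENE = "ncbigene"


class ParseError(ValueError):
    """Raised for malformed XML input or unbalanced tag fragments."""


@dataclass(frozen=True)
class XRef:
    """A cross-reference from one database record to an identifier in another."""

    target_db: str
    target_id: str

    def __post_init__(self) -> None:
        if not self.target_db or not self.target_db.strip():
            raise ValueError("XRef.target_db must be non-empty")
        if not self.target_id or not self.target_id.strip():
            raise ValueError("XRef.target_id must be non-empty")


@dataclass(frozen=True)
class TaggedValue:
    """One name- or taxonomy-bearing tag occurrence, in document order.

    Retaining the originating tag lets the declarative tag→ontology-class
    mapping tables (see :mod:`protsyn.alignment`) drive slot assignment,
    instead of the parsers hard-coding the semantics.
    """

    tag: str
    value: str


@dataclass(frozen=True)
class SourceRecord:
    """One parsed protein or gene entity from a single source database.

    ``synonyms`` is the full raw name list of the record — primary name,
    alternative names and synonyms together, exact-string deduplicated in
    document order with casing preserved.  Case-insensitive deduplication
    happens later, at integration time.
    """

    source: Source
    native_id: str
    primary_name: str | None = None
    alt_names: tuple[str, ...] = ()
    synonyms: tuple[str, ...] = ()
    tax_id: int | None = None
    xrefs: tuple[XRef, ...] = ()
    tagged_values: tuple[TaggedValue, ...] = ()

    def __post_init__(self) -> None:
        if not self.native_id or not self.native_id.strip():
            raise ValueError("SourceRecord.native_id must be non-empty")
        for s in self.synonyms:
            if not s or not s.strip():
                raise ValueError("SourceRecord.synonyms must not contain empty strings")
        if self.tax_id is not None and self.tax_id <= 0:
            raise ValueError("SourceRecord.tax_id must be a positive integer")


# ---------------------------------------------------------------------------
# helpers

StreamLike = Union[str, Path, IO[bytes]]


def open_xml(path: Union[str, Path]) -> IO[bytes]:
    """Open an XML file for streaming, transparently handling gzip."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rb")  # type: ignore[return-value]
    return open(path, "rb")


def _localname(elem: etree._Element) -> str:
    tag = elem.tag
    if isinstance(tag, str) and tag.startswith("{"):
        return tag.rsplit("}", 1)[1]
    return tag if isinstance(tag, str) else ""


def _text(elem: etree._Element | None) -> str:
    if elem is None or elem.text is None:
        return ""
    return elem.text.strip()


def _find(elem: etree._Element, *names: str) -> etree._Element | None:
    """Depth-first search by local names, one level per name."""
    node: etree._Element | None = elem
    for name in names:
        if node is None:
            return None
        node = next((c for c in node if _localname(c) == name), None)
    return node


def _findall(elem: etree._Element, name: str) -> list[etree._Element]:
    return [c for c in elem if _localname(c) == name]


def _iterdescendants(elem: etree._Element, name: str) -> Iterator[etree._Element]:
    for node in elem.iter():
        if node is not elem and _localname(node) == name:
            yield node


def _dedup(values: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for v in values:
        if v and v not in seen:
            seen[v] = None
    return tuple(seen)


def _iterparse(stream: StreamLike, record_tag: str) -> Iterator[etree._Element]:
    """Yield each complete element with the given local name, then free it."""
    close = False
    if isinstance(stream, (str, Path)):
        stream = open_xml(stream)
        close = True
    try:
        try:
            for _event, elem in etree.iterparse(stream, events=("end",), recover=False):
                if _localname(elem) == record_tag:
                    yield elem
                    # release the processed subtree and preceding siblings so
                    # memory stays bounded per record
                    elem.clear()
                    parent = elem.getparent()
                    if parent is not None:
                        while elem.getprevious() is not None:
                            del parent[0]
        except etree.XMLSyntaxError as exc:
            raise ParseError(f"malformed XML: {exc}") from exc
    finally:
        if close:
            stream.close()


def _parse_tax(raw: str, context: str) -> int | None:
    try:
        tax = int(raw)
    except ValueError:
        logger.warning("%s: non-numeric taxonomy id %r ignored", context, raw)
        return None
    if tax <= 0:
        logger.warning("%s: non-positive taxonomy id %r ignored", context, raw)
        return None
    return tax


# ---------------------------------------------------------------------------
# UniProtKB entry XML


def parse_uniprot(stream: StreamLike) -> Iterator[SourceRecord]:
    """Parse UniProtKB entry XML into :class:`SourceRecord` values.

    One record per ``<entry>``: the primary name comes from
    ``<recommendedName>``, alternative and gene-synonym names populate
    ``alt_names``/``synonyms``, the tax id from the NCBI-Taxonomy
    ``<dbReference>``, and entry-level ``<dbReference>`` elements (GeneID
    among them) become cross-references.  Entries without an
    ``<accession>`` are skipped with a logged error.
    """
    for entry in _iterparse(stream, "entry"):
        accession = _text(_find(entry, "accession"))
        if not accession:
            logger.error("uniprot: <entry> without <accession> skipped")
            continue

        tagged: list[TaggedValue] = []
        alt_names: list[str] = []

        protein = _find(entry, "protein")
        recommended = ""
        if protein is not None:
            rec = _find(protein, "recommendedName")
            recommended = _text(_find(rec, "fullName")) if rec is not None else ""
            if not recommended and rec is not None:
                recommended = _text(rec)
            if recommended:
                tagged.append(TaggedValue("recommendedName", recommended))
            for alt in _findall(protein, "alternativeName"):
                name = _text(_find(alt, "fullName")) or _text(alt)
                if name:
                    alt_names.append(name)
                    tagged.append(TaggedValue("alternativeName", name))

        gene = _find(entry, "gene")
        if gene is not None:
            for name_el in _findall(gene, "name"):
                kind = name_el.get("type", "")
                name = _text(name_el)
                if not name:
                    continue
                if kind == "primary":
                    tagged.append(TaggedValue("PrimaryName", name))
                elif kind == "synonym":
                    tagged.append(TaggedValue("synonymName", name))

        tax_id: int | None = None
        organism = _find(entry, "organism")
        if organism is not None:
            for ref in _findall(organism, "dbReference"):
                if ref.get("type") == "NCBI Taxonomy" and ref.get("id"):
                    tax_id = _parse_tax(ref.get("id", ""), f"uniprot:{accession}")
                    if tax_id is not None:
                        tagged.append(TaggedValue("NCBI TaxonomyId", str(tax_id)))
                    break

        xrefs = tuple(
            XRef(ref.get("type", ""), ref.get("id", ""))
            for ref in _findall(entry, "dbReference")
            if ref.get("type") and ref.get("id")
        )

        names = [tv.value for tv in tagged if tv.tag != "NCBI TaxonomyId"]
        yield SourceRecord(
            source=Source.UNIPROT,
            native_id=accession,
            primary_name=recommended or None,
            alt_names=tuple(alt_names),
            synonyms=_dedup(names),
            tax_id=tax_id,
            xrefs=xrefs,
            tagged_values=tuple(tagged),
        )


# ---------------------------------------------------------------------------
# BioGRID PSI-MI 2.5 interactor XML


def parse_biogrid(stream: StreamLike) -> Iterator[SourceRecord]:
    """Parse PSI-MI 2.5 interactor XML into :class:`SourceRecord` values.

    One record per ``<interactor>``: primary name from ``<shortLabel>``,
    synonyms from ``<alias>`` elements, tax id from the organism
    ``ncbiTaxId`` attribute (absent tax id is kept, with a warning, rather
    than dropping the record), cross-references from ``<xref>`` refs.
    """
    for interactor in _iterparse(stream, "interactor"):
        native_id = interactor.get("id", "").strip()
        if not native_id:
            logger.error("biogrid: <interactor> without id attribute skipped")
            continue

        tagged: list[TaggedValue] = []
        names_el = _find(interactor, "names")
        short_label = ""
        aliases: list[str] = []
        if names_el is not None:
            short_label = _text(_find(names_el, "shortLabel"))
            if short_label:
                tagged.append(TaggedValue("shortLabel", short_label))
            for alias in _findall(names_el, "alias"):
                value = _text(alias)
                if value:
                    aliases.append(value)
                    tagged.append(TaggedValue("alias", value))

        tax_id: int | None = None
        organism = _find(interactor, "organism")
        if organism is not None and organism.get("ncbiTaxId"):
            tax_id = _parse_tax(organism.get("ncbiTaxId", ""), f"biogrid:{native_id}")
        if tax_id is not None:
            tagged.append(TaggedValue("ncbiTaxId", str(tax_id)))
        else:
            logger.warning("biogrid: interactor %s has no ncbiTaxId", native_id)

        xrefs: list[XRef] = []
        xref_el = _find(interactor, "xref")
        if xref_el is not None:
            for ref in xref_el:
                if _localname(ref) in ("primaryRef", "secondaryRef"):
                    db = ref.get("db", "")
                    rid = ref.get("id", "")
                    if db and rid:
                        xrefs.append(XRef(db, rid))

        yield SourceRecord(
            source=Source.BIOGRID,
            native_id=native_id,
            primary_name=short_label or None,
            alt_names=(),
            synonyms=_dedup([short_label, *aliases]),
            tax_id=tax_id,
            xrefs=tuple(xrefs),
            tagged_values=tuple(tagged),
        )


# ---------------------------------------------------------------------------
# NCBI Entrezgene XML


def parse_ncbigene(stream: StreamLike) -> Iterator[SourceRecord]:
    """Parse Entrezgene-dialect XML into :class:`SourceRecord` values.

    One record per ``<Entrezgene>``: native id from ``<GeneID>``, primary
    name from ``<Symbol>``, synonyms split from the ``;``-separated
    ``<Synonyms>`` field, tax id from ``<TaxID>``, cross-references from
    ``<dbXrefs>``.  Genes without a GeneID are skipped with a logged error.
    """
    for gene in _iterparse(stream, "Entrezgene"):
        gene_id = _text(_find(gene, "GeneID"))
        if not gene_id:
            logger.error("ncbigene: <Entrezgene> without <GeneID> skipped")
            continue

        tagged: list[TaggedValue] = []
        symbol = _text(_find(gene, "Symbol"))
        if symbol:
            tagged.append(TaggedValue("Symbol", symbol))

        raw_synonyms = _text(_find(gene, "Synonyms"))
        synonyms = [s.strip() for s in raw_synonyms.split(";") if s.strip()]
        for s in synonyms:
            tagged.append(TaggedValue("Synonym", s))

        tax_id: int | None = None
        raw_tax = _text(_find(gene, "TaxID"))
        if raw_tax:
            tax_id = _parse_tax(raw_tax, f"ncbigene:{gene_id}")
        if tax_id is not None:
            tagged.append(TaggedValue("taxId", str(tax_id)))

        xrefs: list[XRef] = []
        dbxrefs = _find(gene, "dbXrefs")
        if dbxrefs is not None:
            for ref in dbxrefs:
                db = ref.get("db", "")
                rid = ref.get("id", "")
                if db and rid:
                    xrefs.append(XRef(db, rid))

        yield SourceRecord(
            source=Source.NCBIGENE,
            native_id=gene_id,
            primary_name=symbol or None,
            alt_names=(),
            synonyms=_dedup([symbol, *synonyms]),
            tax_id=tax_id,
            xrefs=tuple(xrefs),
            tagged_values=tuple(tagged),
        )


# ---------------------------------------------------------------------------
# tag-value extraction


def extract_tag_value(fragment: str, tag: str) -> str:
    """Return the text between ``<tag>`` and ``</tag>`` in an XML fragment.

    The value of a tag is the content between its opening and closing form,
    with surrounding whitespace stripped; an absent tag yields the empty
    string.  Whitespace inside the angle brackets is tolerated (printed
    fragments such as ``<TaxID > 8355 </TaxID >`` parse correctly).

    Raises :class:`ParseError` if the tag is unbalanced (an opening tag
    without its closing tag, or vice versa).
    """
    esc = re.escape(tag)
    open_re = re.compile(rf"<\s*{esc}(?:\s[^<>/]*)?\s*>")
    close_re = re.compile(rf"<\s*/\s*{esc}\s*>")

    open_m = open_re.search(fragment)
    close_m = close_re.search(fragment)
    if open_m is None and close_m is None:
        return ""
    if open_m is None or close_m is None:
        raise ParseError(f"unbalanced tag <{tag}> in fragment")
    if close_m.start() < open_m.end():
        raise ParseError(f"closing </{tag}> precedes opening <{tag}>")
    return fragment[open_m.end() : close_m.start()].strip()
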