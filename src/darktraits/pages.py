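"""Page-parallel extraction contract and topological document reconstruction.

Long documents are discretized into per-page visual units and extracted
concurrently; results are then reassembled strictly in original page order,
so the reconstructed document is a pure function of its pages and the
extractor — never of thread count or completion order.  Cross-page tables
are merged conservatively: only adjacent tables showing clear structural
continuation (equal column count, headerless continuation or verbatim
header repetition) are joined; ambiguous boundaries stay separate.

The extractor is an injection point (:class:`ExtractorContract`).  Tests and
the synthetic pipeline use :class:`ScriptedExtractor`, which replays
pre-serialized page blocks from corpus files — the structural behaviour of a
vision backend without any model call.
"""

from __future__ import annotations

import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Protocol, Sequence

from .errors import DuplicatePageIndex, ExtractorFailure, MissingPage

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PageUnit:
    """One page of a document; raster metadata stands in for pixel data."""

    page_index: int  # 1-based
    raster_dpi: int = 300


@dataclass(frozen=True)
class ExtractionTemplate:
    """Schema constraint applied uniformly to every page."""

    fields: tuple[tuple[str, str], ...] = (
        ("species", "text"),
        ("traits", "table"),
    )
    version: str = "1"


@dataclass(frozen=True)
class TableBlock:
    headers: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]
    has_header: bool = True

    def __post_init__(self) -> None:
        ncol = len(self.headers) if self.has_header else (
            len(self.rows[0]) if self.rows else 0
        )
        for row in self.rows:
            if len(row) != ncol:
                raise ValueError("table rows must be rectangular")

    @property
    def n_columns(self) -> int:
        return len(self.headers) if self.has_header else (
            len(self.rows[0]) if self.rows else 0
        )

    @property
    def n_cells(self) -> int:
        return sum(len(r) for r in self.rows)


@dataclass(frozen=True)
class Block:
    block_index: int
    kind: str  # text | table | caption
    payload: object  # TableBlock for tables, str otherwise


@dataclass(frozen=True)
class PageExtraction:
    page_index: int
    blocks: tuple[Block, ...] = ()
    malformed: bool = False
    retries_used: int = 0


@dataclass(frozen=True)
class PlacedBlock:
    page_index: int
    block_index: int
    kind: str
    payload: object


@dataclass
class DocumentAggregate:
    """All blocks of a document in (page_index, block_index) order."""

    blocks: list[PlacedBlock] = field(default_factory=list)
    merge_log: list[tuple[int, int, bool, str]] = field(default_factory=list)

    def tables(self) -> list[PlacedBlock]:
        return [b for b in self.blocks if b.kind == "table"]

    def total_table_cells(self) -> int:
        return sum(b.payload.n_cells for b in self.tables())


class ExtractorContract(Protocol):
    """Single integration point for any page-level extraction backend."""

    def __call__(
        self, page: PageUnit, template: ExtractionTemplate
    ) -> PageExtraction: ...


# --------------------------------------------------------------------------
# concurrent extraction
# --------------------------------------------------------------------------


def extract_pages(
    pages: Sequence[PageUnit],
    extractor: ExtractorContract,
    template: ExtractionTemplate = ExtractionTemplate(),
    concurrency: int = 4,
    max_retries: int = 2,
) -> list[PageExtraction]:
    """Extract every page concurrently; one result per page, keyed and
    ordered by page index regardless of completion order.

    Malformed outputs are re-attempted up to ``max_retries`` times under the
    same schema-constrained settings, then emitted with ``malformed=True``.
    An extractor exception surfaces as a malformed extraction for that page
    only; the document is never aborted.
    """
    if concurrency < 1:
        raise ValueError("concurrency must be >= 1")

    def _one(page: PageUnit) -> PageExtraction:
        last: Optional[PageExtraction] = None
        for attempt in range(max_retries + 1):
            try:
                result = extractor(page, template)
            except Exception as exc:  # ExtractorFailure surfaces per page
                last = PageExtraction(page.page_index, (), malformed=True,
                                      retries_used=attempt)
                continue
            if result.page_index != page.page_index:
                result = replace(result, page_index=page.page_index)
            if not result.malformed:
                return replace(result, retries_used=attempt)
            last = replace(result, retries_used=attempt)
        assert last is not None
        return last

    with ThreadPoolExecutor(max_workers=concurrency) as pool:
        results = list(pool.map(_one, pages))
    return sorted(results, key=lambda r: r.page_index)


# --------------------------------------------------------------------------
# topological reconstruction
# --------------------------------------------------------------------------


def reconstruct_sequence(
    extractions: Sequence[PageExtraction],
) -> DocumentAggregate:
    """Concatenate page blocks in strict (page_index, block_index) order.

    Raises :class:`DuplicatePageIndex` or :class:`MissingPage` when the page
    set is not exactly 1..N; no block is lost or duplicated.
    """
    seen: set[int] = set()
    for e in extractions:
        if e.page_index in seen:
            raise DuplicatePageIndex(f"page {e.page_index} appears twice")
        seen.add(e.page_index)
    if seen:
        expected = set(range(1, max(seen) + 1))
        missing = expected - seen
        if missing:
            raise MissingPage(f"missing pages: {sorted(missing)}")

    aggregate = DocumentAggregate()
    for e in sorted(extractions, key=lambda x: x.page_index):
        for b in sorted(e.blocks, key=lambda x: x.block_index):
            aggregate.blocks.append(
                PlacedBlock(e.page_index, b.block_index, b.kind, b.payload)
            )
    return aggregate


def _is_continuation(prev: TableBlock, nxt: TableBlock) -> tuple[bool, str]:
    if prev.n_columns != nxt.n_columns:
        return False, "column_mismatch"
    if not nxt.has_header:
        return True, "headerless_continuation"
    if tuple(nxt.headers) == tuple(prev.headers):
        return True, "repeated_header"
    return False, "header_mismatch"


def merge_table_continuations(aggregate: DocumentAggregate) -> DocumentAggregate:
    """Merge cross-page table continuations conservatively.

    A merge happens iff the last block of page *i* and the first block of
    page *i+1* are both tables, with equal column counts, and the
    continuation either lacks a header row or repeats the previous header
    verbatim (the duplicate header is dropped).  Every other adjacent table
    pair is kept separate with the reason recorded.  Associative across
    runs spanning three or more pages; idempotent; total non-header cell
    count is conserved.
    """
    out = DocumentAggregate(merge_log=list(aggregate.merge_log))
    by_page: dict[int, list[PlacedBlock]] = {}
    for b in aggregate.blocks:
        by_page.setdefault(b.page_index, []).append(b)
    page_order = sorted(by_page)

    for page in page_order:
        blocks = by_page[page]
        if (
            out.blocks
            and blocks
            and out.blocks[-1].kind == "table"
            and blocks[0].kind == "table"
            and page - 1 in by_page
            and by_page[page - 1]
            and by_page[page - 1][-1].kind == "table"
        ):
            prev_placed = out.blocks[-1]
            nxt = blocks[0].payload
            merged, reason = _is_continuation(prev_placed.payload, nxt)
            out.merge_log.append((page - 1, page, merged, reason))
            if merged:
                combined = TableBlock(
                    headers=prev_placed.payload.headers,
                    rows=prev_placed.payload.rows + nxt.rows,
                    has_header=prev_placed.payload.has_header,
                )
                out.blocks[-1] = PlacedBlock(
                    prev_placed.page_index,
                    prev_placed.block_index,
                    "table",
                    combined,
                )
                blocks = blocks[1:]
        out.blocks.extend(blocks)
    return out


# --------------------------------------------------------------------------
# corpus serialization and the scripted extractor
# --------------------------------------------------------------------------


def _block_to_json(block: Block) -> dict:
    if block.kind == "table":
        t: TableBlock = block.payload
        payload = {
            "headers": list(t.headers),
            "rows": [list(r) for r in t.rows],
            "has_header": t.has_header,
        }
    else:
        payload = {"text": block.payload}
    return {"block_index": block.block_index, "kind": block.kind,
            "payload": payload}


def _block_from_json(data: dict) -> Block:
    if data["kind"] == "table":
        p = data["payload"]
        payload: object = TableBlock(
            headers=tuple(p["headers"]),
            rows=tuple(tuple(c) for c in p["rows"]),
            has_header=p["has_header"],
        )
    else:
        payload = data["payload"]["text"]
    return Block(data["block_index"], data["kind"], payload)


def write_page_file(path: Path, extraction: PageExtraction) -> None:
    data = {
        "page_index": extraction.page_index,
        "blocks": [_block_to_json(b) for b in extraction.blocks],
    }
    path.write_text(json.dumps(data, indent=1), encoding="utf-8")


def read_page_file(path: Path) -> PageExtraction:
    data = json.loads(path.read_text(encoding="utf-8"))
    return PageExtraction(
        page_index=data["page_index"],
        blocks=tuple(_block_from_json(b) for b in data["blocks"]),
    )


class ScriptedExtractor:
    """Deterministic fixture extractor replaying pre-serialized page blocks.

    One document = one directory of ``page_NNNN.json`` files in the corpus
    dialect above.  ``fail_pages`` maps a page index to a number of scripted
    malformed attempts before a valid output, exercising the retry policy.
    """

    def __init__(
        self,
        document_dir: str | Path,
        fail_pages: Optional[dict[int, int]] = None,
    ) -> None:
        self.document_dir = Path(document_dir)
        self.fail_pages = dict(fail_pages or {})
        self._attempts: dict[int, int] = {}

    def pages(self) -> list[PageUnit]:
        indices = sorted(
            int(p.stem.split("_")[1]) for p in self.document_dir.glob("page_*.json")
        )
        return [PageUnit(i) for i in indices]

    def __call__(
        self, page: PageUnit, template: ExtractionTemplate
    ) -> PageExtraction:
        n = self._attempts.get(page.page_index, 0)
        self._attempts[page.page_index] = n + 1
        if n < self.fail_pages.get(page.page_index, 0):
            return PageExtraction(page.page_index, (), malformed=True)
        path = self.document_dir / f"page_{page.page_index:04d}.json"
        if not path.exists():
            raise ExtractorFailure(f"no scripted output for page {page.page_index}")
        return read_page_file(path)


def extract_document(
    document_dir: str | Path,
    concurrency: int = 4,
    max_retries: int = 2,
) -> DocumentAggregate:
    """Scripted end-to-end reconstruction of one corpus document."""
    extractor = ScriptedExtractor(document_dir)
    pages = extractor.pages()
    extractions = extract_pages(
        pages, extractor, concurrency=concurrency, max_retries=max_retries
    )
    return merge_table_continuations(reconstruct_sequence(extractions))
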