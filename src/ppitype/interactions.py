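"""MITAB interaction records and unique protein pairs.

Reads PSI-MI TAB 2.5 files, collapses redundant records to unique unordered
protein pairs with merged annotations, and propagates detection-method and
interaction-type annotations through their controlled-vocabulary ancestors.
Interactor identifiers are the raw column-1/2 primary ids with the database
prefix stripped ("uniprotkb:P04637" -> "P04637"); no cross-database mapping
is attempted.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "UniqueInteraction",
    "read_mitab",
    "deduplicate",
    "propagate",
    "map_assay_types",
    "write_interaction_table",
    "read_interaction_table",
]

# psi-mi:"MI:0018"(two hybrid) — accession inside the quoted field
_MI_ACCESSION = re.compile(r'(MI:\d{4})')


@dataclass
class InteractionRecord:
    id_a: str
    id_b: str
    methods: set[str] = field(default_factory=set)
    types: set[str] = field(default_factory=set)
    source: str = ""


@dataclass
class UniqueInteraction:
    """An unordered protein pair with merged, closure-propagated annotations."""

    pair: tuple[str, str]
    methods_direct: set[str] = field(default_factory=set)
    methods_closed: set[str] = field(default_factory=set)
    types_direct: set[str] = field(default_factory=set)
    types_closed: set[str] = field(default_factory=set)
    n_source_records: int = 0

    @property
    def pair_id(self) -> str:
        return f"{self.pair[0]}--{self.pair[1]}"


def _strip_prefix(identifier: str) -> str:
    """'uniprotkb:P04637' -> 'P04637'; ids without a prefix pass through."""
    _, sep, rest = identifier.partition(":")
    return rest if sep and rest else identifier


def _parse_cv_field(text: str, line_no: int, column: str) -> set[str]:
    if text in ("-", ""):
        return set()
    out: set[str] = set()
    for part in text.split("|"):
        m = _MI_ACCESSION.search(part)
        if m:
            out.add(m.group(1))
        else:
            logger.warning(
                "line %d: malformed MI accession in %s field: %r (skipped)",
                line_no, column, part,
            )
    return out


def read_mitab(stream: IO[str] | str | Path) -> list[InteractionRecord]:
    """Parse MITAB 2.5 lines into :class:`InteractionRecord` objects.

    Columns 1-2 carry interactor ids, column 7 the detection method(s) and
    column 12 the interaction type(s), each as ``psi-mi:"MI:NNNN"(name)``
    possibly pipe-delimited.  Lines with fewer than 12 columns are rejected
    with a warning; malformed accessions drop that annotation only.
    """
    if isinstance(stream, (str, Path)):
        path = Path(stream)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:  # type: ignore[operator]
            return read_mitab(fh)
    records = []
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            logger.warning("line %d: fewer than 12 columns, rejected", line_no)
            continue
        id_a, id_b = _strip_prefix(cols[0]), _strip_prefix(cols[1])
        if not id_a or not id_b:
            logger.warning("line %d: empty interactor id, rejected", line_no)
            continue
        records.append(
            InteractionRecord(
                id_a=id_a,
                id_b=id_b,
                methods=_parse_cv_field(cols[6], line_no, "detection-method"),
                types=_parse_cv_field(cols[11], line_no, "interaction-type"),
                source=cols[12] if len(cols) > 12 else "",
            )
        )
    return records


def deduplicate(records: Iterable[InteractionRecord]) -> list[UniqueInteraction]:
    """Group records by canonical unordered pair and merge annotations.

    Self-pairs (A, A) are retained.  The result is sorted by pair, so the
    output is independent of input record order.
    """
    merged: dict[tuple[str, str], UniqueInteraction] = {}
    for rec in records:
        pair = tuple(sorted((rec.id_a, rec.id_b)))
        ui = merged.get(pair)
        if ui is None:
            ui = merged[pair] = UniqueInteraction(pair=pair)
        ui.methods_direct |= rec.methods
        ui.types_direct |= rec.types
        ui.n_source_records += 1
    return [merged[p] for p in sorted(merged)]


def propagate(
    ontology_methods: Ontology,
    ontology_types: Ontology,
    interactions: Iterable[UniqueInteraction],
) -> list[UniqueInteraction]:
    """Fill ``methods_closed``/``types_closed`` with is_a ancestor closures.

    Terms absent from the respective ontology are dropped from the closed
    set with a warning (they stay in the direct set).  Idempotent.
    """
    interactions = list(interactions)
    for ui in interactions:
        ui.methods_closed = set(
            ontology_methods.closure(_known(ontology_methods, ui.methods_direct))
        )
        ui.types_closed = set(
            ontology_types.closure(_known(ontology_types, ui.types_direct))
        )
    return interactions


def _known(ontology: Ontology, terms: set[str]) -> set[str]:
    unknown = {t for t in terms if t not in ontology}
    for t in sorted(unknown):
        logger.warning("term %s absent from ontology, dropped from closure", t)
    return terms - unknown


def map_assay_types(
    interactions: Iterable[UniqueInteraction],
    assay_to_type: Mapping[str, str],
    ontology_methods: Ontology,
    ontology_types: Ontology,
) -> list[UniqueInteraction]:
    """Add interaction types implied by type-specific assays.

    Enzymatic-study assays (phosphatase assay, cleavage assay, ...) detect a
    single reaction type; an interaction whose direct methods include a
    mapped assay gains the mapped type, and closures are recomputed.
    Unknown terms in the mapping are a hard error.
    """
    for assay, itype in assay_to_type.items():
        if assay not in ontology_methods:
            raise ValueError(f"assay term {assay!r} not in method ontology")
        if itype not in ontology_types:
            raise ValueError(f"type term {itype!r} not in type ontology")
    interactions = list(interactions)
    for ui in interactions:
        hit = ui.methods_direct & set(assay_to_type)
        if hit:
            ui.types_direct |= {assay_to_type[a] for a in hit}
    return propagate(ontology_methods, ontology_types, interactions)


def _fmt_set(s: set[str]) -> str:
    return "|".join(sorted(s)) if s else "-"


def write_interaction_table(
    interactions: Iterable[UniqueInteraction], stream: IO[str]
) -> None:
    """Write the canonical interaction table TSV (sets pipe-delimited, sorted)."""
    stream.write(
        "pair_a\tpair_b\tmethods_direct\tmethods_closed\t"
        "types_direct\ttypes_closed\tn_source_records\n"
    )
    for ui in interactions:
        stream.write(
            "\t".join(
                [
                    ui.pair[0],
                    ui.pair[1],
                    _fmt_set(ui.methods_direct),
                    _fmt_set(ui.methods_closed),
                    _fmt_set(ui.types_direct),
                    _fmt_set(ui.types_closed),
                    str(ui.n_source_records),
                ]
            )
            + "\n"
        )


def _parse_set(text: str) -> set[str]:
    return set() if text == "-" else set(text.split("|"))


def read_interaction_table(stream: IO[str]) -> list[UniqueInteraction]:
    header = stream.readline()
    if not header.startswith("pair_a\t"):
        raise ValueError("not an interaction table (bad header)")
    out = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        a, b, md, mc, td, tc, n = line.split("\t")
        out.append(
            UniqueInteraction(
                pair=(a, b),
                methods_direct=_parse_set(md),
                methods_closed=_parse_set(mc),
                types_direct=_parse_set(td),
                types_closed=_parse_set(tc),
                n_source_records=int(n),
            )
        )
    return out
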