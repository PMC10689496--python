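"""Binary cognate matrices: loading, validation, concept merging, ascertainment.

A cognate matrix codes, for every language, whether it attests each cognate
set (1), lacks it (0), or its cognacy is uncertain (?).  Cognate sets are
grouped into meaning concepts ("hand", "go", ...), the partition unit for
per-concept evolutionary rates and for the ascertainment correction that
compensates for latent, never-attested cognate sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

PRESENT, ABSENT, MISSING = 1, 0, 2
_SYMBOL_TO_CODE = {"1": PRESENT, "0": ABSENT, "?": MISSING}
_CODE_TO_SYMBOL = {PRESENT: "1", ABSENT: "0", MISSING: "?"}
ASC_ID = "ascertainment"


@dataclass
class ConceptMergeRule:
    source_concepts: list[str]
    target_concept: str


@dataclass
class CognateMatrix:
    """Languages x cognate-set matrix partitioned into meaning concepts.

    ``cells`` is int8 with codes 1=present, 0=absent, 2=uncertain('?'),
    shape (n_languages, n_columns).
    """

    languages: list[str]
    tip_dates: dict[str, float]
    column_concepts: list[str]
    column_ids: list[str]
    cells: np.ndarray
    is_ascertainment: np.ndarray = field(default=None)  # bool per column

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.is_ascertainment is None:
            self.is_ascertainment = np.zeros(self.cells.shape[1], dtype=bool)
        self.is_ascertainment = np.asarray(self.is_ascertainment, dtype=bool)
        self.validate()

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        n_lang, n_cols = self.cells.shape
        if len(self.languages) != n_lang:
            raise ValueError("language count does not match matrix rows")
        if len(set(self.languages)) != n_lang:
            raise ValueError("duplicate language name")
        if len(self.column_concepts) != n_cols or len(self.column_ids) != n_cols:
            raise ValueError("column annotation length mismatch")
        if any(not c for c in self.column_concepts):
            raise ValueError("column with no concept id")
        bad = ~np.isin(self.cells, [PRESENT, ABSENT, MISSING])
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"invalid cell value at language {self.languages[i]!r}, "
                f"column {self.column_ids[j]!r}"
            )
        for lang, date in self.tip_dates.items():
            if date < 0:
                raise ValueError(f"negative tip date for {lang}")
        for lang in self.languages:
            if lang not in self.tip_dates:
                raise ValueError(f"missing tip date for {lang}")
        # at most one ascertainment column per concept, and it must be all-absent
        asc_concepts = [c for c, a in zip(self.column_concepts, self.is_ascertainment) if a]
        if len(asc_concepts) != len(set(asc_concepts)):
            raise ValueError("multiple ascertainment columns for one concept")
        asc_cols = self.cells[:, self.is_ascertainment]
        if asc_cols.size and (asc_cols != ABSENT).any():
            raise ValueError("ascertainment columns must be all-absent")
        for concept in self.concepts:
            mask = (np.asarray(self.column_concepts) == concept) & ~self.is_ascertainment
            if not mask.any():
                raise ValueError(f"concept {concept!r} has no data column")

    # -- derived views -------------------------------------------------------

    @property
    def concepts(self) -> list[str]:
        seen, out = set(), []
        for c in self.column_concepts:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    @property
    def n_languages(self) -> int:
        return len(self.languages)

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_data_columns(self) -> int:
        return int((~self.is_ascertainment).sum())

    def concept_index(self) -> np.ndarray:
        """Integer concept index per column, following `concepts` order."""
        order = {c: i for i, c in enumerate(self.concepts)}
        return np.array([order[c] for c in self.column_concepts], dtype=np.int64)

    def copy(self) -> "CognateMatrix":
        return CognateMatrix(
            languages=list(self.languages),
            tip_dates=dict(self.tip_dates),
            column_concepts=list(self.column_concepts),
            column_ids=list(self.column_ids),
            cells=self.cells.copy(),
            is_ascertainment=self.is_ascertainment.copy(),
        )

    def equals(self, other: "CognateMatrix") -> bool:
        return (
            self.languages == other.languages
            and self.tip_dates == other.tip_dates
            and self.column_concepts == other.column_concepts
            and self.column_ids == other.column_ids
            and np.array_equal(self.cells, other.cells)
            and np.array_equal(self.is_ascertainment, other.is_ascertainment)
        )


# -- operations --------------------------------------------------------------


def merge_concepts(m: CognateMatrix, rules: list[ConceptMergeRule]) -> CognateMatrix:
    """Reassign columns of each rule's source concepts to its target concept.

    Mirrors the combination of synonymous meaning classes (e.g. the motion
    verbs sharing roots); cells are untouched, only the partition changes.
    """
    present = set(m.concepts)
    seen_sources: set[str] = set()
    for rule in rules:
        for s in rule.source_concepts:
            if s not in present:
                raise ValueError(f"merge rule references missing concept {s!r}")
            if s in seen_sources:
                raise ValueError(f"concept {s!r} appears in multiple rules")
            seen_sources.add(s)
    mapping = {s: r.target_concept for r in rules for s in r.source_concepts}
    new_concepts = [mapping.get(c, c) for c in m.column_concepts]
    # merged concepts may inherit several ascertainment columns; keep the first
    keep, seen_asc = [], set()
    for j, (concept, asc) in enumerate(zip(new_concepts, m.is_ascertainment)):
        if asc:
            if concept in seen_asc:
                continue
            seen_asc.add(concept)
        keep.append(j)
    return CognateMatrix(
        languages=list(m.languages),
        tip_dates=dict(m.tip_dates),
        column_concepts=[new_concepts[j] for j in keep],
        column_ids=[m.column_ids[j] for j in keep],
        cells=m.cells[:, keep].copy(),
        is_ascertainment=m.is_ascertainment[keep].copy(),
    )


def add_ascertainment_columns(m: CognateMatrix) -> CognateMatrix:
    """Append one all-absent column per concept, flagged is_ascertainment."""
    if m.is_ascertainment.any():
        raise ValueError("ascertainment columns already present")
    extra = len(m.concepts)
    cells = np.concatenate(
        [m.cells, np.full((m.n_languages, extra), ABSENT, dtype=np.int8)], axis=1
    )
    return CognateMatrix(
        languages=list(m.languages),
        tip_dates=dict(m.tip_dates),
        column_concepts=list(m.column_concepts) + list(m.concepts),
        column_ids=list(m.column_ids) + [f"{c}__asc" for c in m.concepts],
        cells=cells,
        is_ascertainment=np.concatenate(
            [np.zeros(m.cells.shape[1], dtype=bool), np.ones(extra, dtype=bool)]
        ),
    )


def matrix_summary(m: CognateMatrix) -> dict:
    data = m.cells[:, ~m.is_ascertainment]
    return {
        "n_languages": m.n_languages,
        "n_concepts": m.n_concepts,
        "n_cognate_sets": m.n_data_columns,
        "per_language_presences": {
            lang: int((data[i] == PRESENT).sum()) for i, lang in enumerate(m.languages)
        },
        "missing_fraction": float((data == MISSING).mean()) if data.size else 0.0,
    }


# -- CSV dialect -------------------------------------------------------------
# Row 1: language,date_bp,<concept id per column>...
# Row 2: ,,<cognate id per column>...
# Then one row per language: name,date,cells.  Ascertainment columns carry the
# cognate id suffix "__asc".


def write_cognate_csv(m: CognateMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("language,date_bp," + ",".join(m.column_concepts) + "\n")
        fh.write(",," + ",".join(m.column_ids) + "\n")
        for i, lang in enumerate(m.languages):
            row = [_CODE_TO_SYMBOL[int(v)] for v in m.cells[i]]
            fh.write(f"{lang},{m.tip_dates[lang]:g}," + ",".join(row) + "\n")


def _read_cognate_csv(path) -> CognateMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header1, header2 = lines[0].split(","), lines[1].split(",")
    concepts, ids = header1[2:], header2[2:]
    languages, dates, rows = [], {}, []
    for ln in lines[2:]:
        parts = ln.split(",")
        languages.append(parts[0])
        dates[parts[0]] = float(parts[1])
        row = []
        for j, sym in enumerate(parts[2:]):
            if sym not in _SYMBOL_TO_CODE:
                raise ValueError(
                    f"unknown symbol {sym!r} at language {parts[0]!r}, column {ids[j]!r}"
                )
            row.append(_SYMBOL_TO_CODE[sym])
        rows.append(row)
    is_asc = np.array([cid.endswith("__asc") for cid in ids], dtype=bool)
    return CognateMatrix(
        languages=languages,
        tip_dates=dates,
        column_concepts=concepts,
        column_ids=ids,
        cells=np.array(rows, dtype=np.int8),
        is_ascertainment=is_asc,
    )


# -- NEXUS dialect -----------------------------------------------------------
# DATA block with datatype=standard symbols="01" missing=?, plus a SETS block
# holding one charset per concept and an `ascertainment` charset.


def write_cognate_nexus(m: CognateMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={m.n_languages} NCHAR={m.cells.shape[1]};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n  MATRIX\n')
        width = max(len(l) for l in m.languages) + 2
        for i, lang in enumerate(m.languages):
            row = "".join(_CODE_TO_SYMBOL[int(v)] for v in m.cells[i])
            fh.write(f"    {lang:<{width}}{row}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        concept_arr = np.asarray(m.column_concepts)
        for concept in m.concepts:
            idx = np.flatnonzero(concept_arr == concept) + 1
            fh.write(f"  CHARSET {_nexus_safe(concept)} = {_ranges(idx)};\n")
        asc_idx = np.flatnonzero(m.is_ascertainment) + 1
        if asc_idx.size:
            fh.write(f"  CHARSET ascertainment = {_ranges(asc_idx)};\n")
        fh.write("END;\n\nBEGIN URHEIMAT;\n")
        for lang in m.languages:
            fh.write(f"  TIPDATE {lang} = {m.tip_dates[lang]:g};\n")
        fh.write("END;\n")


def _nexus_safe(s: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.]", "_", s)


def _ranges(idx: np.ndarray) -> str:
    """1-based positions -> NEXUS range list like '1-3 7 9-10'."""
    out, start, prev = [], None, None
    for i in idx:
        if start is None:
            start = prev = i
        elif i == prev + 1:
            prev = i
        else:
            out.append(f"{start}-{prev}" if prev > start else f"{start}")
            start = prev = i
    if start is not None:
        out.append(f"{start}-{prev}" if prev > start else f"{start}")
    return " ".join(out)


def _read_cognate_nexus(path) -> CognateMatrix:
    with open(path) as fh:
        text = fh.read()
    matrix_block = re.search(r"MATRIX\s*(.*?);", text, re.S | re.I).group(1)
    languages, rows = [], []
    for ln in matrix_block.strip().splitlines():
        parts = ln.split()
        if len(parts) != 2:
            continue
        languages.append(parts[0])
        row = []
        for j, sym in enumerate(parts[1]):
            if sym not in _SYMBOL_TO_CODE:
                raise ValueError(
                    f"unknown symbol {sym!r} at language {parts[0]!r}, position {j + 1}"
                )
            row.append(_SYMBOL_TO_CODE[sym])
        rows.append(row)
    cells = np.array(rows, dtype=np.int8)
    n_cols = cells.shape[1]

    column_concepts = [""] * n_cols
    is_asc = np.zeros(n_cols, dtype=bool)
    for mobj in re.finditer(r"CHARSET\s+(\S+)\s*=\s*([^;]+);", text, re.I):
        name, spec = mobj.group(1), mobj.group(2)
        positions = []
        for token in spec.split():
            if "-" in token:
                a, b = token.split("-")
                positions.extend(range(int(a), int(b) + 1))
            else:
                positions.append(int(token))
        if name.lower() == ASC_ID:
            for p in positions:
                is_asc[p - 1] = True
        else:
            for p in positions:
                column_concepts[p - 1] = name

    tip_dates = {}
    for mobj in re.finditer(r"TIPDATE\s+(\S+)\s*=\s*([0-9.eE+-]+);", text):
        tip_dates[mobj.group(1)] = float(mobj.group(2))
    if not tip_dates:
        tip_dates = {lang: 0.0 for lang in languages}

    column_ids = [
        f"{c}__asc" if a else f"{c}_{j + 1}"
        for j, (c, a) in enumerate(zip(column_concepts, is_asc))
    ]
    return CognateMatrix(
        languages=languages,
        tip_dates=tip_dates,
        column_concepts=column_concepts,
        column_ids=column_ids,
        cells=cells,
        is_ascertainment=is_asc,
    )


def load_cognate_matrix(path, format: str = "csv") -> CognateMatrix:
    if format == "csv":
        return _read_cognate_csv(path)
    if format == "nexus":
        return _read_cognate_nexus(path)
    raise ValueError(f"unknown format {format!r}")
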