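"""Cross-link and monolink tables: I/O, deduplication, domain
classification, contact maps, condition comparison, covariation overlap.

Residue coordinates are 1-based inclusive throughout, matching the
residue numbering conventions of the source data (e.g. K34, E208).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .linker_chemistry import CrosslinkerSpec, REGISTRY

XL_COLUMNS = [
    "protein_a", "residue_a", "restype_a",
    "protein_b", "residue_b", "restype_b",
    "chemistry", "condition",
]
OPTIONAL_XL_COLUMNS = ["score", "intermolecular"]

MONOLINK_COLUMNS = ["protein", "residue", "restype", "chemistry", "condition"]


@dataclass(frozen=True)
class CrosslinkRecord:
    """One identified cross-link between two residues.

    The pair is unordered: ``(a, b)`` and ``(b, a)`` denote the same
    physical link. ``intermolecular`` records whether the link is known
    intra- or intermolecular; homo-oligomeric samples cannot distinguish
    the two, so the default is "ambiguous".
    """

    protein_a: str
    residue_a: int
    restype_a: str
    protein_b: str
    residue_b: int
    restype_b: str
    chemistry: str
    condition: str
    score: float | None = None
    intermolecular: str = "ambiguous"
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise ValueError("residue positions must be >= 1")
        if self.intermolecular not in ("intra", "inter", "ambiguous"):
            raise ValueError(f"bad intermolecular tag {self.intermolecular!r}")

    @property
    def pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Canonical unordered (protein, residue) pair, sorted."""
        a = (self.protein_a, self.residue_a)
        b = (self.protein_b, self.residue_b)
        return (a, b) if a <= b else (b, a)

    def is_valid(self, spec: CrosslinkerSpec) -> bool:
        """Residue types consistent with the chemistry's reactive pair."""
        return spec.reactive_compatible(self.restype_a, self.restype_b)


@dataclass(frozen=True)
class MonolinkRecord:
    """A single-ended cross-linker modification marking surface reactivity."""

    protein: str
    residue: int
    restype: str
    chemistry: str
    condition: str

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise ValueError("residue position must be >= 1")


@dataclass(frozen=True)
class DomainMap:
    """Ordered, non-overlapping 1-based inclusive domain intervals.

    ``subfeatures`` carries optional annotations (e.g. a helix inside a
    domain) reported alongside, never instead of, the domain label.
    """

    domains: tuple[tuple[str, int, int], ...]
    subfeatures: tuple[tuple[str, int, int], ...] = ()
    metadata: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        spans = sorted((s, e, n) for n, s, e in self.domains)
        for (s, e, n) in spans:
            if s < 1 or e < s:
                raise ValueError(f"bad interval for domain {n!r}: ({s}, {e})")
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"domains {n1!r} and {n2!r} overlap")

    def domain_of(self, residue: int) -> str | None:
        for name, start, end in self.domains:
            if start <= residue <= end:
                return name
        return None

    def subfeatures_of(self, residue: int) -> list[str]:
        return [n for n, s, e in self.subfeatures if s <= residue <= e]


def dnajb8_domain_map(gf_st_boundary: int = 139,
                      h5: tuple[int, int] | None = None) -> DomainMap:
    """Default DnaJB8 domain map: JD 1-82, G/F 83-..., S/T ...-169,
    CTD 170-232. The G/F vs S/T boundary is approximate and configurable;
    an H5 helix interval inside G/F may be supplied for sub-feature
    annotation."""
    if not 83 <= gf_st_boundary <= 168:
        raise ValueError("G/F boundary must lie in [83, 168]")
    sub = (("H5", h5[0], h5[1]),) if h5 is not None else ()
    return DomainMap(
        domains=(
            ("JD", 1, 82),
            ("G/F", 83, gf_st_boundary),
            ("S/T", gf_st_boundary + 1, 169),
            ("CTD", 170, 232),
        ),
        subfeatures=sub,
        metadata=(("gf_st_boundary", "approximate"),),
    )


# ---------------------------------------------------------------- I/O

def read_xl_table(path: str) -> list[CrosslinkRecord]:
    """Read a TSV cross-link table.

    Mandatory columns: protein_a, residue_a, restype_a, protein_b,
    residue_b, restype_b, chemistry, condition. Optional: score,
    intermolecular. Unknown columns are preserved in ``extra``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in XL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns
                  if c not in XL_COLUMNS + OPTIONAL_XL_COLUMNS]
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            rec = CrosslinkRecord(
                protein_a=row["protein_a"],
                residue_a=int(row["residue_a"]),
                restype_a=row["restype_a"],
                protein_b=row["protein_b"],
                residue_b=int(row["residue_b"]),
                restype_b=row["restype_b"],
                chemistry=row["chemistry"],
                condition=row["condition"],
                score=float(row["score"]) if row.get("score", "") != "" else None,
                intermolecular=row.get("intermolecular", "") or "ambiguous",
                extra=tuple((c, row[c]) for c in extra_cols),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed row at line {line}: {exc}") from exc
        records.append(rec)
    return records


def write_xl_table(records: Sequence[CrosslinkRecord], path: str) -> None:
    extra_cols: list[str] = []
    for rec in records:
        for col, _ in rec.extra:
            if col not in extra_cols:
                extra_cols.append(col)
    rows = []
    for rec in records:
        row = {
            "protein_a": rec.protein_a, "residue_a": rec.residue_a,
            "restype_a": rec.restype_a,
            "protein_b": rec.protein_b, "residue_b": rec.residue_b,
            "restype_b": rec.restype_b,
            "chemistry": rec.chemistry, "condition": rec.condition,
            "score": "" if rec.score is None else rec.score,
            "intermolecular": rec.intermolecular,
        }
        row.update(dict(rec.extra))
        rows.append(row)
    cols = XL_COLUMNS + OPTIONAL_XL_COLUMNS + extra_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_monolink_table(path: str) -> list[MonolinkRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MONOLINK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(MonolinkRecord(
                protein=row["protein"], residue=int(row["residue"]),
                restype=row["restype"], chemistry=row["chemistry"],
                condition=row["condition"],
            ))
        except ValueError as exc:
            raise ValueError(f"malformed row at line {idx + 2}: {exc}") from exc
    return records


def write_monolink_table(records: Sequence[MonolinkRecord], path: str) -> None:
    pd.DataFrame(
        [{c: getattr(r, c) for c in MONOLINK_COLUMNS} for r in records],
        columns=MONOLINK_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------- core operations

def chemistry_class(chemistry: str,
                    registry: dict[str, CrosslinkerSpec] | None = None) -> str:
    """Group chemistries by reactive-pair class so that e.g. two acid-acid
    linkers dedup together; unknown chemistries form their own class."""
    reg = REGISTRY if registry is None else registry
    spec = reg.get(chemistry)
    if spec is None:
        return chemistry
    sa, sb = sorted(("".join(sorted(spec.reactive_pair[0])),
                     "".join(sorted(spec.reactive_pair[1]))))
    return f"{sa}x{sb}"


PairKey = tuple[str, str, tuple[tuple[str, int], tuple[str, int]]]


def deduplicate(records: Iterable[CrosslinkRecord],
                registry: dict[str, CrosslinkerSpec] | None = None
                ) -> dict[PairKey, list[CrosslinkRecord]]:
    """Collapse records to unique unordered residue pairs, keyed by
    (chemistry class, condition, pair). Duplicate identifications across
    charge states and peptide forms collapse onto one key."""
    groups: dict[PairKey, list[CrosslinkRecord]] = {}
    for rec in records:
        key = (chemistry_class(rec.chemistry, registry), rec.condition, rec.pair)
        groups.setdefault(key, []).append(rec)
    return groups


def unique_pairs(records: Iterable[CrosslinkRecord],
                 condition: str | None = None,
                 registry: dict[str, CrosslinkerSpec] | None = None
                 ) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Unique unordered residue pairs, optionally restricted to one
    condition (chemistry classes pooled)."""
    return {
        rec.pair for rec in records
        if condition is None or rec.condition == condition
    }


def classify_pair(pair: tuple[int, int], domain_map: DomainMap
                  ) -> tuple[str, list[str]]:
    """Domain-class label for a residue pair, plus sub-feature annotations.

    The label is "X–Y" with domain names in lexicographic order, so the
    classification is symmetric. A residue outside every interval yields
    "unassigned" for its side.
    """
    da = domain_map.domain_of(pair[0]) or "unassigned"
    db = domain_map.domain_of(pair[1]) or "unassigned"
    lo, hi = sorted((da, db))
    annotations = sorted(
        set(domain_map.subfeatures_of(pair[0]))
        | set(domain_map.subfeatures_of(pair[1]))
    )
    return f"{lo}–{hi}", annotations


@dataclass
class ContactMap:
    """Symmetric sparse residue-pair contact map with per-pair class labels.

    ``counts`` maps a canonical (low residue, high residue) pair to the
    number of deduplicated link identifications supporting it; the
    diagonal is excluded.
    """

    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    labels: dict[tuple[int, int], str] = field(default_factory=dict)
    annotations: dict[tuple[int, int], list[str]] = field(default_factory=dict)

    @property
    def class_counts(self) -> Counter:
        return Counter(self.labels.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"residue_a": a, "residue_b": b, "count": c,
             "class": self.labels[(a, b)],
             "annotations": ";".join(self.annotations.get((a, b), []))}
            for (a, b), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["residue_a", "residue_b", "count", "class",
                           "annotations"])


def contact_map(records: Iterable[CrosslinkRecord], domain_map: DomainMap,
                registry: dict[str, CrosslinkerSpec] | None = None
                ) -> ContactMap:
    """Build a contact map from records (deduplicated internally).

    Self-links (same residue on both sides) are excluded. Per-class
    counts sum to the number of unique off-diagonal pairs.
    """
    cmap = ContactMap()
    for (_cls, _cond, pair), recs in deduplicate(records, registry).items():
        (pa, ra), (pb, rb) = pair
        if (pa, ra) == (pb, rb):
            continue
        key = (ra, rb) if ra <= rb else (rb, ra)
        cmap.counts[key] = cmap.counts.get(key, 0) + len(recs)
        label, annotations = classify_pair(key, domain_map)
        cmap.labels[key] = label
        cmap.annotations[key] = annotations
    return cmap


def compare_conditions(records: Iterable[CrosslinkRecord],
                       cond_a: str, cond_b: str
                       ) -> dict[str, set]:
    """Partition the union of two conditions' unique pairs into
    shared / a_only / b_only sets. Raises if a condition tag is absent."""
    records = list(records)
    seen = {rec.condition for rec in records}
    for cond in (cond_a, cond_b):
        if cond not in seen:
            raise ValueError(f"condition {cond!r} not present in records")
    pa = unique_pairs(records, cond_a)
    pb = unique_pairs(records, cond_b)
    return {"shared": pa & pb, "a_only": pa - pb, "b_only": pb - pa}


def monolink_frequency(monolinks: Iterable[MonolinkRecord],
                       condition: str | None = None
                       ) -> Counter:
    """Counts of monolink identifications per (residue, chemistry)."""
    return Counter(
        (m.residue, m.chemistry) for m in monolinks
        if condition is None or m.condition == condition
    )


def compare_monolink_conditions(monolinks: Iterable[MonolinkRecord],
                                cond_a: str, cond_b: str) -> pd.DataFrame:
    """Paired-condition monolink report with per-residue count differences."""
    monolinks = list(monolinks)
    fa = monolink_frequency(monolinks, cond_a)
    fb = monolink_frequency(monolinks, cond_b)
    keys = sorted(set(fa) | set(fb))
    return pd.DataFrame(
        [{"residue": r, "chemistry": c,
          "count_a": fa.get((r, c), 0), "count_b": fb.get((r, c), 0),
          "difference": fa.get((r, c), 0) - fb.get((r, c), 0)}
         for r, c in keys],
        columns=["residue", "chemistry", "count_a", "count_b", "difference"])


def read_covariation_table(path: str) -> pd.DataFrame:
    """Read a covarying-residue-pair table (columns: i, j, probability)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("i", "j", "probability"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column(s): {col}")
    if ((df["probability"] < 0) | (df["probability"] > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return df


def covariation_overlap(pairs: Iterable[tuple[int, int]],
                        covar_table: pd.DataFrame,
                        prob_threshold: float = 0.7,
                        window: int = 2) -> dict:
    """Overlap between cross-link pairs and high-confidence covarying pairs.

    A cross-link (a, b) overlaps if some covarying pair with probability
    >= ``prob_threshold`` lies within ±``window`` residues on both
    coordinates, in either orientation. Returns the overlap count and the
    fraction of cross-links overlapped.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pairs = list(pairs)
    strong = covar_table[covar_table["probability"] >= prob_threshold]
    ci = strong["i"].to_numpy()
    cj = strong["j"].to_numpy()
    overlapped = []
    for a, b in pairs:
        hit = (
            ((abs(ci - a) <= window) & (abs(cj - b) <= window))
            | ((abs(ci - b) <= window) & (abs(cj - a) <= window))
        ).any()
        overlapped.append(bool(hit))
    count = sum(overlapped)
    return {
        "count": count,
        "fraction": count / len(pairs) if pairs else 0.0,
        "overlapped": overlapped,
    }
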