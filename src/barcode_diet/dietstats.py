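"""Size-class diet composition and bookkeeping over the clone-count table.

This is the results layer of the pipeline: given the OTU x sample clone
table (with per-OTU lineage and identification level) and the per-sample
predator records (lengths, mass, PCR outcome), it computes PCR success
bookkeeping, per-sample prey richness, taxon-class composition, taxonomic
richness rollups, and the overlap of prey OTU sets among predator size
classes (total length < 100 mm, 100-199 mm, >= 200 mm).

Composition is presence-based (OTU counts, not clone abundance): clone
libraries give presence/absence evidence, so clone multiplicities are used
only for bookkeeping, never as abundance weights.  The predator's own
(self-DNA) OTU is retained by default so published-style totals reproduce;
``exclude_self`` recomputes everything without it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .refdb import Lineage

__all__ = [
    "SizeClass", "SIZE_CLASSES", "size_class_of", "PredatorRecord",
    "CloneTable", "DietSummary", "load_predator_records", "load_clone_table",
    "pcr_success_rate", "per_sample_richness", "class_composition",
    "richness_rollup", "size_class_overlap", "classes_consumed",
    "exclude_self", "summarize", "render_report", "packaged_fixture_path",
]

log = logging.getLogger(__name__)

DEFAULT_PREDATOR = "Micropterus salmoides"


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SizeClass:
    """Half-open total-length bin: [lower, upper) in mm."""

    label: str
    lower: float
    upper: float

    def __contains__(self, tl_mm: float) -> bool:
        return self.lower <= tl_mm < self.upper


SIZE_CLASSES = (
    SizeClass("I", 0.0, 100.0),
    SizeClass("II", 100.0, 200.0),
    SizeClass("III", 200.0, float("inf")),
)


def size_class_of(tl_mm: float) -> SizeClass:
    if tl_mm <= 0:
        raise ValueError(f"total length must be positive, got {tl_mm}")
    for sc in SIZE_CLASSES:
        if tl_mm in sc:
            return sc
    raise AssertionError("unreachable: bins are exhaustive")


@dataclass(frozen=True)
class PredatorRecord:
    sample_no: int
    sample_id: str
    total_length_mm: float
    body_length_mm: float
    weight_g: float
    date: str
    pcr_status: str  # success | failed | empty_stomach
    n_pcr_attempts: int
    n_clones: int

    def __post_init__(self) -> None:
        if self.pcr_status not in ("success", "failed", "empty_stomach"):
            raise ValidationError(f"bad pcr_status {self.pcr_status!r}")
        if self.body_length_mm <= 0:
            raise ValidationError(f"sample {self.sample_no}: nonpositive body length")
        if self.total_length_mm < self.body_length_mm:
            # occurs in published records (likely a transcription slip);
            # keep the printed values and warn rather than refuse to load
            log.warning("sample %s: TL %.0f mm < BL %.0f mm", self.sample_no,
                        self.total_length_mm, self.body_length_mm)
        if (self.n_clones == 0) != (self.pcr_status in ("failed", "empty_stomach")):
            raise ValidationError(
                f"sample {self.sample_no}: clone count {self.n_clones} inconsistent "
                f"with PCR status {self.pcr_status!r}")

    @property
    def size_class(self) -> SizeClass:
        return size_class_of(self.total_length_mm)


def packaged_fixture_path(name: str) -> Path:
    """Path of a packaged fixture TSV (``table1.tsv`` or ``table2.tsv``)."""
    return Path(resources.files("barcode_diet").joinpath("data", name))


def load_predator_records(table1_path: str | Path | None = None) -> list[PredatorRecord]:
    path = table1_path or packaged_fixture_path("table1.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "date": str})
    return [
        PredatorRecord(int(r.sample_no), r.sample_id, float(r.total_length_mm),
                       float(r.body_length_mm), float(r.weight_g), r.date,
                       r.pcr_status, int(r.n_pcr_attempts), int(r.n_clones))
        for r in df.itertuples()
    ]


@dataclass
class CloneTable:
    """OTU x sample clone-count matrix with per-OTU lineage annotations."""

    otus: pd.DataFrame     # index otu_id; lineage + identity + level columns
    counts: pd.DataFrame   # index otu_id; columns sample_no (int)
    samples: list[PredatorRecord]

    def lineage_of(self, otu_id: str) -> Lineage:
        row = self.otus.loc[otu_id]
        return Lineage(row["phylum"], row["class"], row["order"], row["family"],
                       row["genus"], row["species"])

    def samples_in(self, size_class: SizeClass | str) -> list[PredatorRecord]:
        label = size_class.label if isinstance(size_class, SizeClass) else size_class
        return [s for s in self.samples if s.size_class.label == label]

    def otus_present_in(self, sample_nos: Iterable[int]) -> set[str]:
        cols = [n for n in sample_nos if n in self.counts.columns]
        sub = self.counts[cols]
        return set(sub.index[(sub > 0).any(axis=1)])

    @property
    def matrix_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def load_clone_table(table2_path: str | Path | None = None,
                     table1_path: str | Path | None = None,
                     expected_subtotals: tuple[int, int, int, int] | None = (85, 142, 81, 308),
                     ) -> CloneTable:
    """Load the clone table and predator records, with marginal validation.

    ``expected_subtotals`` are the published per-size-class clone subtotals
    and grand total for the predator records (I, II, III, total); pass None
    to skip the check for non-fixture data.  The count matrix must have one
    column per predator record, with all-zero columns for failed/empty
    samples.  Note the published count matrix undercounts the sequenced
    clones (extra clones from two deeply sequenced guts are not tabulated);
    the matrix total is reported as-is and is deliberately not reconciled
    against the clone subtotals.
    """
    samples = load_predator_records(table1_path)
    path = table2_path or packaged_fixture_path("table2.tsv")
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"otu_id": str})
    if df["otu_id"].duplicated().any():
        raise ValidationError("duplicate otu_id in clone table")
    df = df.set_index("otu_id")
    count_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    counts = df[count_cols].astype(int)
    counts.columns = [int(c[1:]) for c in count_cols]
    otus = df.drop(columns=count_cols)
    if len(counts.columns) != len(samples):
        raise ValidationError(
            f"count matrix has {len(counts.columns)} sample columns, "
            f"expected {len(samples)}")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative clone counts")
    for s in samples:
        if s.pcr_status != "success" and counts[s.sample_no].sum() != 0:
            raise ValidationError(
                f"sample {s.sample_no} is {s.pcr_status} but has nonzero counts")
    if expected_subtotals is not None:
        got = tuple(
            sum(s.n_clones for s in samples if s.size_class.label == lab)
            for lab in ("I", "II", "III")
        )
        got += (sum(s.n_clones for s in samples),)
        if got != expected_subtotals:
            bad = [f"class {lab}: {g} != {e}"
                   for lab, g, e in zip(("I", "II", "III", "total"), got,
                                        expected_subtotals) if g != e]
            raise ValidationError("clone subtotal mismatch: " + "; ".join(bad))
    return CloneTable(otus=otus, counts=counts, samples=samples)


def pcr_success_rate(samples: list[PredatorRecord]) -> float:
    """Percent of non-empty guts successfully amplified (empty stomachs are
    excluded from the denominator)."""
    succ = sum(1 for s in samples if s.pcr_status == "success")
    fail = sum(1 for s in samples if s.pcr_status == "failed")
    if succ + fail == 0:
        raise ValidationError("no amplifiable samples")
    return 100.0 * succ / (succ + fail)


def per_sample_richness(t: CloneTable) -> dict[int, int]:
    """Number of OTUs detected per successfully amplified sample."""
    return {
        s.sample_no: int((t.counts[s.sample_no] > 0).sum())
        for s in t.samples
        if s.pcr_status == "success"
    }


def class_composition(t: CloneTable, size_class: str | None = None
                      ) -> list[tuple[str, int, float]]:
    """OTU counts and percentages per taxon class (Linnean rank 'class').

    Presence-based: each OTU contributes once.  ``size_class`` of None means
    all samples; otherwise only OTUs detected in that size class count.
    Sorted by descending OTU count, then name.
    """
    if size_class is None:
        present = set(t.otus.index)
    else:
        present = t.otus_present_in(
            s.sample_no for s in t.samples_in(size_class))
    total = len(present)
    by_class: dict[str, int] = {}
    for otu_id in present:
        name = t.otus.loc[otu_id, "class"]
        by_class[name] = by_class.get(name, 0) + 1
    return [
        (name, k, 100.0 * k / total)
        for name, k in sorted(by_class.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def richness_rollup(t: CloneTable) -> tuple[int, int, int, int]:
    """Distinct (phyla, classes, orders, families) across all OTUs."""
    if len(t.otus) == 0:
        return (0, 0, 0, 0)
    return tuple(
        int(t.otus[col][t.otus[col] != ""].nunique())
        for col in ("phylum", "class", "order", "family")
    )


def classes_consumed(t: CloneTable) -> dict[str, int]:
    """Distinct taxon classes detected in each predator size class."""
    out = {}
    for sc in SIZE_CLASSES:
        present = t.otus_present_in(s.sample_no for s in t.samples_in(sc))
        out[sc.label] = len({t.otus.loc[o, "class"] for o in present})
    return out


_OVERLAP_CELLS = ("I", "II", "III", "I&II", "I&III", "II&III", "I&II&III")


def size_class_overlap(t: CloneTable) -> dict[str, set[str]]:
    """Partition observed OTUs by their size-class presence pattern.

    Seven disjoint cells (exclusive to one class, each pairwise overlap,
    and the three-way core); every OTU detected in any class lands in
    exactly one cell.
    """
    present = {
        sc.label: t.otus_present_in(s.sample_no for s in t.samples_in(sc))
        for sc in SIZE_CLASSES
    }
    cells: dict[str, set[str]] = {c: set() for c in _OVERLAP_CELLS}
    for otu_id in set().union(*present.values()):
        pattern = [lab for lab in ("I", "II", "III") if otu_id in present[lab]]
        cells["&".join(pattern)].add(otu_id)
    return cells


def exclude_self(t: CloneTable, predator: str = DEFAULT_PREDATOR) -> CloneTable:
    """Copy of the table without the predator's own (self-DNA) OTU rows."""
    keep = t.otus["species"] != predator
    return CloneTable(otus=t.otus[keep].copy(), counts=t.counts[keep.values].copy(),
                      samples=t.samples)


@dataclass
class DietSummary:
    pcr_success_pct: float
    total_clones: int
    matrix_clones: int
    n_otus: int
    n_species_level: int
    species_level_pct: float
    rollup: tuple[int, int, int, int]
    composition_all: list[tuple[str, int, float]]
    composition_by_class: dict[str, list[tuple[str, int, float]]]
    classes_consumed: dict[str, int]
    overlap: dict[str, set[str]]
    per_sample_richness: dict[int, int]
    otus_per_class: dict[str, int] = field(default_factory=dict)


def summarize(t: CloneTable) -> DietSummary:
    n = len(t.otus)
    nsp = int((t.otus["level"] == "species").sum())
    overlap = size_class_overlap(t)
    return DietSummary(
        pcr_success_pct=pcr_success_rate(t.samples),
        total_clones=sum(s.n_clones for s in t.samples),
        matrix_clones=t.matrix_total,
        n_otus=n,
        n_species_level=nsp,
        species_level_pct=100.0 * nsp / n if n else 0.0,
        rollup=richness_rollup(t),
        composition_all=class_composition(t),
        composition_by_class={sc.label: class_composition(t, sc.label)
                              for sc in SIZE_CLASSES},
        classes_consumed=classes_consumed(t),
        overlap=overlap,
        per_sample_richness=per_sample_richness(t),
        otus_per_class={
            sc.label: len(t.otus_present_in(
                s.sample_no for s in t.samples_in(sc)))
            for sc in SIZE_CLASSES
        },
    )


def render_report(summary: DietSummary, out_dir: str | Path,
                  venn: bool = False) -> list[Path]:
    """Write the summary as deterministic TSV tables (plus an optional SVG
    Venn diagram of the size-class OTU overlap)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def table(name: str, header: list[str], rows: Iterable[Iterable]) -> None:
        p = out / name
        with open(p, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        written.append(p)

    table("summary.tsv", ["quantity", "value"], [
        ("pcr_success_pct", f"{summary.pcr_success_pct:.1f}"),
        ("total_clones", summary.total_clones),
        ("matrix_clones", summary.matrix_clones),
        ("n_otus", summary.n_otus),
        ("n_species_level", summary.n_species_level),
        ("species_level_pct", f"{summary.species_level_pct:.1f}"),
        ("n_phyla", summary.rollup[0]),
        ("n_classes", summary.rollup[1]),
        ("n_orders", summary.rollup[2]),
        ("n_families", summary.rollup[3]),
    ])
    comp_rows = [("all", n, k, f"{p:.2f}") for n, k, p in summary.composition_all]
    for lab in ("I", "II", "III"):
        comp_rows += [(lab, n, k, f"{p:.2f}")
                      for n, k, p in summary.composition_by_class[lab]]
    table("composition.tsv", ["scope", "taxon_class", "n_otus", "pct"], comp_rows)
    table("overlap.tsv", ["cell", "n_otus", "otus"], [
        (cell, len(summary.overlap[cell]),
         ",".join(sorted(summary.overlap[cell])))
        for cell in _OVERLAP_CELLS
    ])
    table("per_sample_richness.tsv", ["sample_no", "n_otus"],
          sorted(summary.per_sample_richness.items()))
    if venn:
        written.append(_render_venn(summary, out / "venn.svg"))
    return written


def _render_venn(summary: DietSummary, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 5))
    centers = {"I": (-0.5, 0.3), "II": (0.5, 0.3), "III": (0.0, -0.55)}
    for lab, (x, y) in centers.items():
        ax.add_patch(Circle((x, y), 0.85, fill=False, lw=1.5))
        ax.annotate(f"size class {lab}", (x, y + 0.95), ha="center")
    pos = {"I": (-0.8, 0.45), "II": (0.8, 0.45), "III": (0.0, -0.95),
           "I&II": (0.0, 0.55), "I&III": (-0.5, -0.35), "II&III": (0.5, -0.35),
           "I&II&III": (0.0, 0.0)}
    for cell, (x, y) in pos.items():
        ax.annotate(str(len(summary.overlap[cell])), (x, y),
                    ha="center", fontsize=14)
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.8, 1.8)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path
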