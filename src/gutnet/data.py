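"""Core data types and tabular IO.

Every stage of the pipeline consumes one of four inputs: a genus-level
abundance table (taxa x samples, integer counts), a sample->group mapping,
a taxon->class annotation, and qPCR cycle-threshold records. All files are
UTF-8 tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Closed set of taxon annotation classes.
ANNOTATION_CLASSES = frozenset({"virulent", "symbiotic", "oral", "other"})

#: Genera the study singles out; used as annotation defaults.
DEFAULT_VIRULENT = ("Escherichia", "Enterobacter", "Klebsiella", "Shigella")
DEFAULT_SYMBIOTIC = (
    "Bifidobacterium",
    "Butyrivibrio",
    "Faecalibacterium",
    "Roseburia",
    "Ruminococcus",
    "Lachnospira",
)


class DataError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Iterable[str], kind: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)
    return ids


@dataclass
class AbundanceTable:
    """Taxa-by-samples matrix of non-negative integer counts.

    Invariants (enforced on construction): unique taxon and sample
    identifiers, integral non-negative counts, and no all-zero sample
    column (a sample with zero total reads carries no compositional
    information and would corrupt prevalence and CLR downstream).
    """

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples)

    def __post_init__(self) -> None:
        self.taxa = _check_unique(self.taxa, "taxon")
        self.samples = _check_unique(self.samples, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.taxa), len(self.samples)):
            raise DataError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            as_float = counts.astype(float)
            if not np.all(np.isfinite(as_float)):
                raise DataError("counts contain non-finite values")
            if not np.all(as_float == np.round(as_float)):
                raise DataError("counts must be integral (fractional values rejected)")
            counts = as_float.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise DataError("counts must be non-negative")
        colsums = counts.sum(axis=0)
        if counts.size and np.any(colsums == 0):
            bad = [self.samples[i] for i in np.nonzero(colsums == 0)[0]]
            raise DataError(f"all-zero sample column(s): {bad}")
        self.counts = counts

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample sequencing depth (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_samples(self, keep: Iterable[str]) -> "AbundanceTable":
        keep = list(keep)
        idx = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise DataError(f"unknown sample(s): {missing}")
        cols = [idx[s] for s in keep]
        return AbundanceTable(list(self.taxa), keep, self.counts[:, cols])

    def subset_taxa(self, keep: Iterable[str]) -> "AbundanceTable":
        keep = list(keep)
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in keep if t not in idx]
        if missing:
            raise DataError(f"unknown taxon(-a): {missing}")
        rows = [idx[t] for t in keep]
        return AbundanceTable(keep, list(self.samples), self.counts[rows, :])


@dataclass
class SampleGroups:
    """Mapping sample identifier -> group label (e.g. CRC vs relative)."""

    labels: dict[str, str]

    def groups(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        out: list[str] = []
        for v in self.labels.values():
            if v not in out:
                out.append(v)
        return out

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]

    def validate_against(self, table: AbundanceTable, min_per_group: int = 2) -> None:
        missing = [s for s in table.samples if s not in self.labels]
        if missing:
            raise DataError(f"samples without a group label: {missing}")
        for g in self.groups():
            n = sum(1 for s in table.samples if self.labels.get(s) == g)
            if 0 < n < min_per_group:
                raise DataError(f"group {g!r} has only {n} sample(s) in the table")


@dataclass
class TaxonAnnotation:
    """Mapping taxon -> class in {virulent, symbiotic, oral, other}.

    Taxa absent from the mapping default to "other": the study annotates
    only a handful of genera of interest.
    """

    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in ANNOTATION_CLASSES}
        if bad:
            raise DataError(
                f"annotation class(es) {sorted(bad)} outside {sorted(ANNOTATION_CLASSES)}"
            )

    def of(self, taxon: str) -> str:
        return self.classes.get(taxon, "other")

    @classmethod
    def default(cls) -> "TaxonAnnotation":
        """Annotation seeded with the study's virulent/symbiotic genera."""
        mapping = {t: "virulent" for t in DEFAULT_VIRULENT}
        mapping.update({t: "symbiotic" for t in DEFAULT_SYMBIOTIC})
        return cls(mapping)


@dataclass
class CtRecord:
    """One qPCR measurement: target and all-bacteria cycle thresholds."""

    sample: str
    target: str
    ct_target: float
    ct_all_bacteria: float

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target), ("ct_all_bacteria", self.ct_all_bacteria)):
            v = float(v)
            if not np.isfinite(v) or v <= 0:
                raise DataError(f"{name} must be finite and > 0, got {v}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_abundance_table(path: str | Path, orientation: str = "taxa_rows") -> AbundanceTable:
    """Read a tab-separated count table.

    The first column holds identifiers, the header row the other axis.
    A leading BIOM-style ``#OTU ID`` header cell is accepted. With
    ``orientation="samples_rows"`` the file is transposed after reading so
    the returned table is always taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    skip = 1 if first.startswith("# Constructed") else 0  # BIOM-TSV comment line
    frame = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip, comment=None)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if orientation == "samples_rows":
        frame = frame.T
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise DataError(f"non-numeric counts in column {col!r}")
    return AbundanceTable.from_frame(frame)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame.index.name = "taxon"
    frame.to_csv(path, sep="\t", lineterminator="\n")


def _read_two_column(path: str | Path, kind: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated columns")
            key, value = parts[0].strip(), parts[1].strip()
            if lineno == 1 and key.lower() in ("sample", "taxon", "id", "identifier"):
                continue  # optional header
            if key in mapping and mapping[key] != value:
                raise DataError(
                    f"{kind} {key!r} repeated with conflicting labels "
                    f"({mapping[key]!r} vs {value!r})"
                )
            mapping[key] = value
    return mapping


def read_groups(path: str | Path) -> SampleGroups:
    """Read a two-column TSV (sample, group label); header optional."""
    return SampleGroups(_read_two_column(path, "sample"))


def read_annotation(path: str | Path) -> TaxonAnnotation:
    """Read a two-column TSV (taxon, class); classes must be in the closed set."""
    return TaxonAnnotation(_read_two_column(path, "taxon"))


def write_groups(groups: SampleGroups, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s, g in groups.labels.items():
            fh.write(f"{s}\t{g}\n")


def write_annotation(annotation: TaxonAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t, c in annotation.classes.items():
            fh.write(f"{t}\t{c}\n")


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read qPCR records: TSV with columns sample, target, ct_target, ct_all."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample", "target", "ct_target", "ct_all"}
    if not required.issubset(frame.columns):
        raise DataError(f"ct table must have columns {sorted(required)}")
    return [
        CtRecord(str(r["sample"]), str(r["target"]), float(r["ct_target"]), float(r["ct_all"]))
        for _, r in frame.iterrows()
    ]


# ---------------------------------------------------------------------------


def relative_abundance(table: AbundanceTable) -> np.ndarray:
    """Per-sample proportions: each column sums to 1, zeros preserved."""
    counts = table.counts.astype(float)
    return counts / counts.sum(axis=0, keepdims=True)


def mean_relative_abundance(table: AbundanceTable) -> np.ndarray:
    """Mean over samples of per-sample proportions (the node-size attribute)."""
    return relative_abundance(table).mean(axis=1)
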