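"""Readers and writers for the formats the pipeline touches.

Count matrices come in as TSV (first column gene id, header row of sample
ids) or MatrixMarket coordinate files with one-column sidecar gene/sample
name files.  Sample metadata is a CSV with columns ``sample``, ``donor``,
``il6``, ``sil6r``, ``inhibitor``.  Gene sets use the standard GMT dialect.

Gene identifiers are plain case-sensitive strings; matching across files is
exact — no symbol/Ensembl translation is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

log = logging.getLogger("transsig")

INHIBITORS = ("none", "olamkicept", "tocilizumab")

#: canonical condition labels, keyed by (il6, sil6r, inhibitor)
_CONDITION_NAMES = {
    (False, False, "none"): "control",
    (True, False, "none"): "il6",
    (False, True, "none"): "sil6r",
    (True, True, "none"): "il6_sil6r",
    (True, True, "olamkicept"): "il6_sil6r_olamkicept",
    (True, True, "tocilizumab"): "il6_sil6r_tocilizumab",
}
CONDITIONS = tuple(_CONDITION_NAMES.values())


class ValidationError(ValueError):
    """A structurally invalid input (dimensions, labels, value ranges)."""


class ParseError(ValueError):
    """A malformed file that cannot be interpreted at all."""


def condition_name(il6: bool, sil6r: bool, inhibitor: str) -> str:
    key = (bool(il6), bool(sil6r), str(inhibitor))
    if key in _CONDITION_NAMES:
        return _CONDITION_NAMES[key]
    # uncommon combinations (e.g. inhibitor without stimulation) get a
    # systematic composite label rather than an error
    parts = [p for p, on in (("il6", il6), ("sil6r", sil6r)) if on] or ["control"]
    if inhibitor != "none":
        parts.append(inhibitor)
    return "_".join(parts)


@dataclass
class CountExperiment:
    """A gene x sample integer count matrix with its per-sample design.

    ``design`` is indexed by sample id with columns ``donor`` (categorical),
    ``il6`` / ``sil6r`` (bool) and ``inhibitor`` (one of ``none``,
    ``olamkicept``, ``tocilizumab``).
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)[pd.Index(self.genes).duplicated()]
            raise ValidationError(f"duplicate gene identifiers: {list(dupes[:5])}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = self.counts - np.floor(self.counts)
            if np.any(frac != 0):
                g, s = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.genes[g]!r}, "
                    f"sample {self.samples[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.genes[g]!r}, sample {self.samples[s]!r}"
            )
        missing = set(self.samples) - set(self.design.index)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)}")
        extra = set(self.design.index) - set(self.samples)
        if extra:
            raise ValidationError(f"metadata samples absent from counts: {sorted(extra)}")
        self.design = self.design.loc[self.samples]
        for col in ("donor", "il6", "sil6r", "inhibitor"):
            if col not in self.design.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        bad = set(self.design["inhibitor"]) - set(INHIBITORS)
        if bad:
            raise ValidationError(f"unknown inhibitor value(s): {sorted(bad)}")
        if self.design["donor"].isna().any():
            raise ValidationError("every sample must have a donor")
        self.design = self.design.assign(
            il6=self.design["il6"].astype(bool), sil6r=self.design["sil6r"].astype(bool)
        )
        if not (self.condition_labels() == "control").any():
            raise ValidationError(
                "at least one control sample (il6=False, sil6r=False, "
                "inhibitor=none) is required"
            )

    def condition_labels(self) -> pd.Series:
        """Canonical condition label per sample."""
        return pd.Series(
            [
                condition_name(r.il6, r.sil6r, r.inhibitor)
                for r in self.design.itertuples()
            ],
            index=self.design.index,
            name="condition",
        )

    def subset_samples(self, mask) -> "CountExperiment":
        keep = np.asarray(mask)
        samples = [s for s, k in zip(self.samples, keep) if k]
        return CountExperiment(
            genes=list(self.genes),
            samples=samples,
            counts=self.counts[:, keep],
            design=self.design.loc[samples],
        )


@dataclass
class GeneSet:
    name: str
    description: str = ""
    genes: list[str] = field(default_factory=list)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene set names")
        for s in self.sets:
            if len(set(s.genes)) != len(s.genes):
                raise ValidationError(f"duplicate genes within set {s.name!r}")

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def _read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, dtype={"donor": str})
    required = {"sample", "donor", "il6", "sil6r", "inhibitor"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata lacks column(s): {sorted(missing)}")
    meta = meta.set_index("sample")
    for col in ("il6", "sil6r"):
        if meta[col].dtype == object:
            meta[col] = meta[col].astype(str).str.lower().isin(("true", "1", "yes"))
        else:
            meta[col] = meta[col].astype(bool)
    return meta


def read_counts(path, format: str = "tsv", metadata_path=None) -> CountExperiment:
    """Load a count matrix plus metadata into a validated experiment.

    For ``format='mtx'`` the companion files ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` must sit next to the matrix.  Sample order follows
    the metadata file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if metadata_path is None:
        raise ValidationError("metadata_path is required")
    meta = _read_metadata(metadata_path)

    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        samples = [str(s) for s in df.columns]
        counts = df.to_numpy()
    elif format == "mtx":
        stem = path.with_suffix("")
        genes_file = stem.with_suffix(".genes.txt")
        samples_file = stem.with_suffix(".samples.txt")
        for f in (genes_file, samples_file):
            if not f.exists():
                raise FileNotFoundError(f)
        mat = scipy.io.mmread(path)
        counts = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        genes = genes_file.read_text().split()
        samples = samples_file.read_text().split()
    else:
        raise ValidationError(f"unknown counts format {format!r}")

    only_meta = [s for s in meta.index if s not in samples]
    if only_meta:
        raise ValidationError(f"metadata sample(s) not in counts: {only_meta}")
    only_counts = [s for s in samples if s not in meta.index]
    if only_counts:
        raise ValidationError(f"counts sample(s) not in metadata: {only_counts}")
    order = [samples.index(s) for s in meta.index]
    exp = CountExperiment(
        genes=genes,
        samples=list(meta.index),
        counts=counts[:, order],
        design=meta,
    )
    log.info("read %d genes x %d samples from %s", len(genes), len(exp.samples), path)
    return exp


def write_counts(exp: CountExperiment, path, format: str = "tsv",
                 metadata_path=None) -> None:
    """Inverse of :func:`read_counts` (used by the simulators and tests)."""
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(exp.counts, index=exp.genes, columns=exp.samples)
        df.index.name = "gene"
        df.to_csv(path, sep="\t")
    elif format == "mtx":
        stem = path.with_suffix("")
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(exp.counts), field="integer")
        stem.with_suffix(".genes.txt").write_text("\n".join(exp.genes) + "\n")
        stem.with_suffix(".samples.txt").write_text("\n".join(exp.samples) + "\n")
    else:
        raise ValidationError(f"unknown counts format {format!r}")
    if metadata_path is not None:
        meta = exp.design.copy()
        meta.index.name = "sample"
        meta.to_csv(metadata_path)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated set per line (name, description,
    genes...).  Duplicate genes within a line are dropped with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                log.warning(
                    "%s:%d: %d duplicate gene(s) in set %s dropped",
                    path, lineno, len(genes) - len(uniq), name,
                )
            sets.append(GeneSet(name=name, description=desc, genes=uniq))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def write_table(records, path, format: str = "tsv") -> None:
    """Write a result table deterministically.

    Column order follows the input frame; floats are serialized with 10
    significant digits; TSV output always carries a header row.
    """
    df = pd.DataFrame(records)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "json":
        def _clean(v):
            if isinstance(v, (np.floating, float)):
                return float(f"{float(v):.10g}")
            if isinstance(v, np.integer):
                return int(v)
            return v
        recs = [
            {k: _clean(v) for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]
        path.write_text(json.dumps(recs, indent=1) + "\n")
    else:
        raise ValidationError(f"unknown table format {format!r}")


def read_table(path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(Path(path).read_text()))
    raise ValidationError(f"unknown table format {format!r}")
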