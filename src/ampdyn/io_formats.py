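"""Readers, writers and the in-memory containers every other module consumes.

The package works on four substrates: an OTU count table (taxa x samples),
a sample design mapping each sample to (time point, replicate, primer region)
plus operational covariates, a rooted branch-length-weighted phylogeny, and
symmetric pairwise distance matrices.  All on-disk formats are plain text:
tab-separated tables, newick trees, and a flat ``key = value`` config format.

Table orientation is fixed as taxa-rows x sample-columns.  Time points are
1-based consecutive integers (months); every time-lag used downstream is a
difference of time points.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("ampdyn")

SUPPORTED_METRICS = ("bray_curtis", "unifrac_unweighted", "unifrac_weighted")

REQUIRED_DESIGN_COLUMNS = ("sample_id", "time_point", "replicate", "region")

#: canonical operational covariates of an activated-sludge plant
KNOWN_COVARIATES = ("temperature", "mlss", "svi", "bod")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


class ValidationError(ValueError):
    """Raised when a parsed artifact violates a domain invariant."""


# ---------------------------------------------------------------------------
# CommunityTable
# ---------------------------------------------------------------------------


@dataclass
class CommunityTable:
    """Non-negative integer read counts, taxa (rows) x samples (columns)."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = list(map(str, self.taxon_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValidationError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            t, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for taxon {self.taxon_ids[t]!r} "
                f"in sample {self.sample_ids[s]!r}"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {name} ids: {dupes}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)].copy()

    def relative_abundances(self) -> np.ndarray:
        """Column-normalized counts: the p_i that Shannon, Bray-Curtis and
        weighted UniFrac all consume."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValidationError(f"samples with zero total counts: {empty}")
        return self.counts / totals

    def select_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


def read_community_table(path: str | Path) -> CommunityTable:
    """Read a tab-separated OTU table: first column taxon id, header row of
    sample ids, integer cells.  Ordering is preserved from the file."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: expected taxon-id column plus >=1 sample column")
        sample_ids = header[1:]
        taxon_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: row has {len(cells)} fields, header has {len(header)}"
                )
            taxon = cells[0]
            row = []
            for sample, cell in zip(sample_ids, cells[1:]):
                try:
                    value = int(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count {cell!r} for taxon "
                        f"{taxon!r}, sample {sample!r}"
                    ) from exc
                if value < 0:
                    raise FormatError(
                        f"{path}:{lineno}: negative count {value} for taxon "
                        f"{taxon!r}, sample {sample!r}"
                    )
                row.append(value)
            taxon_ids.append(taxon)
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no taxon rows")
    return CommunityTable(taxon_ids, sample_ids, np.asarray(rows, dtype=np.int64))


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("taxon_id\t" + "\t".join(table.sample_ids) + "\n")
        for taxon, row in zip(table.taxon_ids, table.counts):
            fh.write(taxon + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# TimeSeriesDesign
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesDesign:
    """Maps each sample to (time_point, replicate, region) plus covariates.

    ``frame`` is indexed by sample_id; ``time_point`` and ``replicate`` are
    integers, ``region`` a categorical label; any further columns are real
    covariates (temperature, MLSS, SVI, BOD, ...) with NaN for missing.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("time_point", "replicate", "region"):
            if col not in df.columns:
                raise ValidationError(
                    f"design missing required column {col!r}; required columns are "
                    f"{list(REQUIRED_DESIGN_COLUMNS)}"
                )
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in design")
        df = df.copy()
        df["time_point"] = df["time_point"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        df["region"] = df["region"].astype(str)
        triples = list(zip(df["time_point"], df["replicate"], df["region"]))
        if len(set(triples)) != len(triples):
            raise ValidationError("duplicate (time_point, replicate, region) triple")
        tps = sorted(df["time_point"].unique())
        if tps != list(range(tps[0], tps[0] + len(tps))):
            warnings.warn("time points are not contiguous", stacklevel=2)
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def time_points(self) -> list[int]:
        return sorted(self.frame["time_point"].unique())

    @property
    def T(self) -> int:
        return len(self.time_points)

    @property
    def regions(self) -> list[str]:
        return sorted(self.frame["region"].unique())

    def replicates(self, region: str) -> list[int]:
        return sorted(self.frame.loc[self.frame["region"] == region, "replicate"].unique())

    def samples_for(
        self,
        region: str | None = None,
        time_point: int | None = None,
        replicate: int | None = None,
    ) -> list[str]:
        mask = pd.Series(True, index=self.frame.index)
        if region is not None:
            mask &= self.frame["region"] == region
        if time_point is not None:
            mask &= self.frame["time_point"] == time_point
        if replicate is not None:
            mask &= self.frame["replicate"] == replicate
        return list(self.frame.index[mask])

    def covariate(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"covariate {name!r} not in design")
        return self.frame[name].astype(float)

    def covariate_matrix(self, names: Sequence[str], sample_ids: Sequence[str]) -> pd.DataFrame:
        return self.frame.loc[list(sample_ids), list(names)].astype(float)


def read_design(path: str | Path) -> TimeSeriesDesign:
    """Read tab-separated metadata; required columns sample_id, time_point,
    replicate, region; further columns become real covariates."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {missing}; required columns are "
            f"{list(REQUIRED_DESIGN_COLUMNS)}"
        )
    df = df.set_index("sample_id")
    for col in df.columns:
        if col not in ("time_point", "replicate", "region"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return TimeSeriesDesign(df)


def write_design(design: TimeSeriesDesign, path: str | Path) -> None:
    design.frame.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """A rooted tree with taxa at the leaves and a non-negative length on
    every edge; the substrate of UniFrac.  Wraps a ``skbio.TreeNode``;
    the given root is treated as the root (no midpoint re-rooting), and
    polytomies are kept as-is."""

    tree: TreeNode

    def __post_init__(self) -> None:
        names = self.leaf_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")
        n_defaulted = 0
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_defaulted += 1
            elif node.length < 0:
                raise ValidationError(f"negative branch length on {node.name!r}")
        if n_defaulted:
            logger.warning("%d branch lengths missing; defaulted to 0", n_defaulted)
        if self.tree.length is None:
            self.tree.length = 0.0

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.tree.tips()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.tips())

    @property
    def total_branch_length(self) -> float:
        return float(
            sum(node.length or 0.0 for node in self.tree.traverse(include_self=False))
        )

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def read_newick(path: str | Path) -> PhyloTree:
    path = Path(path)
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"{path}: invalid newick ({exc})") from exc
    return PhyloTree(tree)


def parse_newick(newick: str) -> PhyloTree:
    try:
        tree = TreeNode.read(io.StringIO(newick), format="newick")
    except Exception as exc:
        raise FormatError(f"invalid newick ({exc})") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity with a metric label.

    All three supported metrics live on [0, 1] (weighted UniFrac is emitted
    in its normalized form).
    """

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix not symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("diagonal not zero")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        if self.metric in SUPPORTED_METRICS and (
            (self.values < -1e-12).any() or (self.values > 1 + 1e-9).any()
        ):
            raise ValidationError(f"{self.metric} values outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.sample_ids.index(a), self.sample_ids.index(b)])

    def reorder(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)], self.metric)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy 'condensed' order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def write_distance_matrix(
    D: DistanceMatrix, path: str | Path, dialect: str = "square"
) -> None:
    """Square dialect: full symmetric TSV with a header row; lower_triangle:
    PHYLIP-style count line then one row per sample.  The metric label is kept
    in a leading ``# metric:`` comment so it survives a round trip."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# metric: {D.metric}\n")
        if dialect == "square":
            fh.write("sample_id\t" + "\t".join(D.sample_ids) + "\n")
            for sid, row in zip(D.sample_ids, D.values):
                fh.write(sid + "\t" + "\t".join(format(v, ".12g") for v in row) + "\n")
        elif dialect == "lower_triangle":
            fh.write(f"{D.n}\n")
            for i, sid in enumerate(D.sample_ids):
                cells = [format(v, ".12g") for v in D.values[i, :i]]
                fh.write("\t".join([sid] + cells).rstrip("\t") + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    metric = "bray_curtis"
    if lines and lines[0].startswith("# metric:"):
        metric = lines[0].split(":", 1)[1].strip()
        lines = lines[1:]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    first = lines[0].split("\t")
    if len(first) == 1 and first[0].isdigit():
        n = int(first[0])
        ids, rows = [], []
        for i, ln in enumerate(lines[1 : n + 1]):
            cells = ln.split("\t")
            ids.append(cells[0])
            rows.append([float(c) for c in cells[1 : i + 1]])
        values = np.zeros((n, n))
        for i, row in enumerate(rows):
            for j, v in enumerate(row):
                values[i, j] = values[j, i] = v
    else:
        ids = first[1:]
        n = len(ids)
        values = np.zeros((n, n))
        for i, ln in enumerate(lines[1 : n + 1]):
            cells = ln.split("\t")
            values[i] = [float(c) for c in cells[1:]]
    return DistanceMatrix(ids, values, metric)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxon -> ranked lineage table (taxon_id plus rank columns).

    Missing cells stay NaN; consumers substitute ``unclassified_<parent>``
    labels at aggregation time.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "taxon_id" not in df.columns:
        raise ValidationError(f"{path}: taxonomy needs a taxon_id column")
    return df.set_index("taxon_id")


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.rename_axis("taxon_id").reset_index().to_csv(path, sep="\t", index=False)


def lineage_label(
    taxonomy: pd.DataFrame, taxon_id: str, rank: str, parent_ranks: Sequence[str] = RANKS
) -> str:
    """Rank label for a taxon, falling back to ``unclassified_<parent>`` built
    from the deepest classified ancestor rank."""
    if taxon_id not in taxonomy.index:
        return f"unclassified_{taxon_id}"
    row = taxonomy.loc[taxon_id]
    value = row.get(rank)
    if isinstance(value, str) and value:
        return value
    upto = list(parent_ranks)[: list(parent_ranks).index(rank)]
    for parent in reversed(upto):
        pv = row.get(parent)
        if isinstance(pv, str) and pv:
            return f"unclassified_{pv}"
    return f"unclassified_{taxon_id}"


# ---------------------------------------------------------------------------
# Flat key-value config
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, object] = {
    "depth": 2125,
    "seed": 0,
    "permutations": 999,
    "rarefaction_iterations": 1000,
    "nmds_starts": 20,
}


def read_config(path: str | Path) -> dict[str, object]:
    """Flat ``key = value`` config; '#' starts a comment.  Values are coerced
    to int, then float, else kept as strings.  CLI flags override these."""
    config = dict(DEFAULT_CONFIG)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        value: object
        try:
            value = int(raw)
        except ValueError:
            try:
                value = float(raw)
            except ValueError:
                value = raw
        config[key] = value
    return config


def write_config(config: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in config.items())
    )
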