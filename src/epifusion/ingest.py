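"""Construction of per-gene multi-omics feature blocks.

Each gene is anchored at its transcription start site (TSS).  Three feature
blocks are built around that anchor:

* a 7 x 40 matrix of log read counts for the seven core histone marks
  (H3K4me1, H3K4me3, H3K9me3, H3K27me3, H3K36me3, H3K27ac, H3K9ac), binned
  at 100 bp over the 4,000 bp window centred on the TSS;
* the ordered CpG methylation fractions (beta values) within 2,000 bp of
  the TSS;
* a 3 x 1016 transcription-factor matrix (TF expression, binding-site
  count, binding score) over a fixed ordered TF catalog, with every
  non-candidate column masked to zero.

Genes are labelled highly expressed (+1, HEG) or lowly expressed (-1, LEG)
by a per-cell-line median split of the expression values, ties going to LEG.

Coordinate conventions: 0-based half-open intervals throughout; bin ``b``
covers ``[tss-2000+100*b, tss-2000+100*(b+1))``; minus-strand windows are
reversed so that bin 0 is always the most upstream bin in transcriptional
direction, and CpG offsets are sign-flipped accordingly.  The CpG window is
the closed interval ``[tss-2000, tss+2000]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

HISTONE_MARKS = (
    "H3K4me1",
    "H3K4me3",
    "H3K9me3",
    "H3K27me3",
    "H3K36me3",
    "H3K27ac",
    "H3K9ac",
)
N_MARKS = len(HISTONE_MARKS)
N_BINS = 40
BIN_SIZE = 100
WINDOW_HALF = 2000  # histone window half-width, bp
CPG_HALF = 2000  # CpG window half-width, bp
N_TFS = 1016


def tf_catalog() -> list[str]:
    """The fixed ordered 1016-entry TF name catalog.

    Shipped as ``data/tf_catalog_synthetic.txt`` — a synthetic stand-in
    name list (the curated human TF catalog it represents is not
    redistributable here); column index in every TF matrix equals catalog
    index.
    """
    text = (
        resources.files("epifusion").joinpath("data/tf_catalog_synthetic.txt").read_text()
    )
    names = text.split()
    if len(names) != N_TFS:
        raise RuntimeError(f"TF catalog must contain {N_TFS} names, found {len(names)}")
    return names


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """A gene's TSS anchor, strand, and expression value."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    expression: float

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be nonnegative")


@dataclass
class HistoneMatrix:
    """7 marks x 40 bins of log read counts, 5'->3' in transcriptional direction."""

    values: np.ndarray
    mark_order: tuple = HISTONE_MARKS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_MARKS, N_BINS):
            raise ValueError(
                f"histone matrix must be {N_MARKS}x{N_BINS}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("histone matrix entries must be finite and >= 0")


@dataclass
class MethylationTrack:
    """Ordered CpG beta values near the TSS; may be empty."""

    offsets: np.ndarray  # relative to TSS, transcriptional direction
    betas: np.ndarray

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.betas = np.asarray(self.betas, dtype=np.float64)
        if self.offsets.shape != self.betas.shape:
            raise ValueError("offsets and betas must have equal length")
        if self.betas.size and (self.betas.min() < 0 or self.betas.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.offsets.size > 1 and not np.all(np.diff(self.offsets) > 0):
            raise ValueError("offsets must be strictly increasing")

    def __len__(self):
        return self.offsets.size


@dataclass
class TFMatrix:
    """3 x 1016 TF feature matrix with a candidate mask.

    Rows: TF expression, binding-site count, binding score.  Columns where
    ``mask`` is False are all zero.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (3, N_TFS):
            raise ValueError(f"TF matrix must be 3x{N_TFS}, got {self.values.shape}")
        if self.mask.shape != (N_TFS,):
            raise ValueError(f"mask must have length {N_TFS}")
        if np.any(self.values[:, ~self.mask] != 0):
            raise ValueError("non-candidate columns must be all zero")


@dataclass
class OmicsExample:
    """One gene's full feature bundle and its HEG/LEG label."""

    gene: GeneRecord
    hm: HistoneMatrix
    me: MethylationTrack
    tf: TFMatrix
    label: int

    def __post_init__(self):
        if self.label not in (+1, -1):
            raise ValueError("label must be +1 (HEG) or -1 (LEG)")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def bin_histone_signal(reads, gene: GeneRecord) -> HistoneMatrix:
    """Bin per-mark read positions (or coverage intervals) around the TSS.

    ``reads`` maps mark name -> either a 1-D array of read 5' positions or
    a sequence of ``(start, end, value)`` coverage intervals whose value is
    the read count on the interval (apportioned to bins by overlap
    fraction).  Entry (m, b) of the result is ``ln(count + 1)``.
    Reads outside the 4,000 bp window are dropped; a window running past
    the chromosome start is zero-padded with a warning.
    """
    counts = np.zeros((N_MARKS, N_BINS))
    win_lo = gene.tss - WINDOW_HALF
    win_hi = gene.tss + WINDOW_HALF
    if win_lo < 0:
        warnings.warn(
            f"window for {gene.gene_id} extends past chromosome start; "
            "missing bins padded with zero counts",
            stacklevel=2,
        )
    for mi, mark in enumerate(HISTONE_MARKS):
        data = reads.get(mark) if hasattr(reads, "get") else None
        if data is None:
            continue
        arr = np.asarray(data)
        if arr.ndim == 1:  # read 5' positions
            pos = arr[(arr >= win_lo) & (arr < win_hi)]
            bins = (pos - win_lo) // BIN_SIZE
            np.add.at(counts[mi], bins.astype(int), 1)
        else:  # (start, end, value) coverage intervals
            for start, end, value in arr:
                length = int(end) - int(start)
                s = max(int(start), win_lo)
                e = min(int(end), win_hi)
                if s >= e or length <= 0:
                    continue
                b_lo = (s - win_lo) // BIN_SIZE
                b_hi = (e - 1 - win_lo) // BIN_SIZE
                for b in range(b_lo, b_hi + 1):
                    ov_lo = max(s, win_lo + b * BIN_SIZE)
                    ov_hi = min(e, win_lo + (b + 1) * BIN_SIZE)
                    counts[mi, b] += value * (ov_hi - ov_lo) / length
    if gene.strand == "-":
        counts = counts[:, ::-1]
    return HistoneMatrix(np.log1p(counts))


def extract_methylation(cpg_calls, gene: GeneRecord) -> MethylationTrack:
    """Retain CpGs within the closed window ``[tss-2000, tss+2000]``.

    ``cpg_calls``: iterable of ``(position, beta)`` or an (n, 2) array.
    Offsets are reported relative to the TSS, increasing in the gene's
    transcriptional direction.  A beta outside [0, 1] raises a ValueError
    naming the offending record.
    """
    rows = list(cpg_calls)
    kept = []
    for i, (pos, beta) in enumerate(rows):
        if not (0.0 <= beta <= 1.0):
            raise ValueError(
                f"beta value {beta} outside [0,1] at record {i} (position {pos})"
            )
        if abs(int(pos) - gene.tss) <= CPG_HALF:
            offset = int(pos) - gene.tss if gene.strand == "+" else gene.tss - int(pos)
            kept.append((offset, float(beta)))
    kept.sort(key=lambda r: r[0])
    if not kept:
        return MethylationTrack(np.empty(0, dtype=int), np.empty(0))
    offs, betas = zip(*kept)
    return MethylationTrack(np.array(offs), np.array(betas))


def build_tf_matrix(tf_table, gene: GeneRecord, catalog: list[str] | None = None) -> TFMatrix:
    """Assemble the 3 x 1016 TF matrix for one gene.

    ``tf_table``: iterable of ``(tf_name, tf_expression, n_binding_sites,
    binding_score)`` for this gene's candidate binding TFs (motif occurrence
    within 200 bp of the TSS, supplied externally).  Unknown TF names raise.
    """
    if catalog is None:
        catalog = tf_catalog()
    index = {name: i for i, name in enumerate(catalog)}
    values = np.zeros((3, N_TFS))
    mask = np.zeros(N_TFS, dtype=bool)
    for name, expr, n_sites, score in tf_table:
        if name not in index:
            raise KeyError(
                f"unknown TF name {name!r}; not in the {len(catalog)}-entry catalog"
            )
        if n_sites < 0 or int(n_sites) != n_sites:
            raise ValueError(f"binding-site count must be a nonnegative integer ({name})")
        col = index[name]
        values[0, col] = expr
        values[1, col] = n_sites
        values[2, col] = score
        mask[col] = True
    return TFMatrix(values, mask)


def label_genes(expressions: pd.Series | dict) -> pd.Series:
    """Median-split HEG/LEG labels: +1 iff strictly above the median.

    Ties (values equal to the median) are assigned to LEG (-1).
    """
    s = pd.Series(expressions, dtype=float)
    if s.empty:
        raise ValueError("label_genes requires at least one gene")
    if len(s) < 2:
        raise ValueError("label_genes requires at least 2 genes")
    med = s.median()
    return pd.Series(np.where(s.values > med, 1, -1), index=s.index, dtype=int)


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class MultiOmicsDataset:
    """A cell line's worth of per-gene feature blocks, in batched form.

    ``tf_idx[i]`` holds the candidate catalog columns of gene i and
    ``tf_vals[i]`` the corresponding (3, n_candidates) values; the dense
    3 x 1016 matrix is recoverable via :meth:`tf_matrix`.
    """

    genes: list[GeneRecord]
    hm: np.ndarray  # (n, 7, 40) log counts
    me_offsets: list[np.ndarray]
    me_betas: list[np.ndarray]
    tf_idx: list[np.ndarray]
    tf_vals: list[np.ndarray]
    labels: np.ndarray  # (n,) in {+1, -1}
    name: str = "cell_line"

    def __len__(self):
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def expressions(self) -> np.ndarray:
        return np.array([g.expression for g in self.genes])

    def tf_matrix(self, i: int) -> TFMatrix:
        values = np.zeros((3, N_TFS))
        mask = np.zeros(N_TFS, dtype=bool)
        values[:, self.tf_idx[i]] = self.tf_vals[i]
        mask[self.tf_idx[i]] = True
        return TFMatrix(values, mask)

    def example(self, i: int) -> OmicsExample:
        return OmicsExample(
            gene=self.genes[i],
            hm=HistoneMatrix(self.hm[i]),
            me=MethylationTrack(self.me_offsets[i], self.me_betas[i]),
            tf=self.tf_matrix(i),
            label=int(self.labels[i]),
        )

    def subset(self, indices) -> "MultiOmicsDataset":
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MultiOmicsDataset(
            genes=[self.genes[i] for i in idx],
            hm=self.hm[idx],
            me_offsets=[self.me_offsets[i] for i in idx],
            me_betas=[self.me_betas[i] for i in idx],
            tf_idx=[self.tf_idx[i] for i in idx],
            tf_vals=[self.tf_vals[i] for i in idx],
            labels=self.labels[idx],
            name=self.name,
        )

    def subset_by_gene_id(self, gene_ids) -> "MultiOmicsDataset":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return self.subset([pos[g] for g in gene_ids])

    def to_npz(self, path) -> None:
        """Serialize to a single ``.npz`` file (no pickling; ragged arrays flattened)."""
        me_lens = np.array([len(o) for o in self.me_offsets])
        tf_lens = np.array([len(i) for i in self.tf_idx])
        np.savez(
            path,
            name=np.array(self.name),
            gene_id=np.array([g.gene_id for g in self.genes]),
            chrom=np.array([g.chrom for g in self.genes]),
            tss=np.array([g.tss for g in self.genes]),
            strand=np.array([g.strand for g in self.genes]),
            expression=np.array([g.expression for g in self.genes]),
            hm=self.hm,
            labels=self.labels,
            me_lens=me_lens,
            me_offsets=np.concatenate(self.me_offsets) if len(self.me_offsets) else np.empty(0, int),
            me_betas=np.concatenate(self.me_betas) if len(self.me_betas) else np.empty(0),
            tf_lens=tf_lens,
            tf_idx=np.concatenate(self.tf_idx) if len(self.tf_idx) else np.empty(0, int),
            tf_vals=np.concatenate([v.ravel() for v in self.tf_vals]) if len(self.tf_vals) else np.empty(0),
        )

    @classmethod
    def from_npz(cls, path) -> "MultiOmicsDataset":
        with np.load(path, allow_pickle=False) as z:
            genes = [
                GeneRecord(str(g), str(c), int(t), str(s), float(e))
                for g, c, t, s, e in zip(
                    z["gene_id"], z["chrom"], z["tss"], z["strand"], z["expression"]
                )
            ]
            me_splits = np.cumsum(z["me_lens"])[:-1]
            tf_splits = np.cumsum(z["tf_lens"])[:-1]
            tf_vals = [
                v.reshape(3, -1)
                for v in np.split(z["tf_vals"], np.cumsum(3 * z["tf_lens"])[:-1])
            ]
            return cls(
                genes=genes,
                hm=z["hm"],
                me_offsets=np.split(z["me_offsets"], me_splits),
                me_betas=np.split(z["me_betas"], me_splits),
                tf_idx=np.split(z["tf_idx"], tf_splits),
                tf_vals=tf_vals,
                labels=z["labels"],
                name=str(z["name"]),
            )

    @classmethod
    def from_examples(cls, examples: list[OmicsExample], name: str = "cell_line"):
        return cls(
            genes=[e.gene for e in examples],
            hm=np.stack([e.hm.values for e in examples]),
            me_offsets=[e.me.offsets for e in examples],
            me_betas=[e.me.betas for e in examples],
            tf_idx=[np.flatnonzero(e.tf.mask) for e in examples],
            tf_vals=[e.tf.values[:, e.tf.mask] for e in examples],
            labels=np.array([e.label for e in examples]),
            name=name,
        )


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------


def read_gene_annotation(bed_path, expression_path) -> list[GeneRecord]:
    """BED6 annotation + expression TSV -> GeneRecords.

    TSS = BED start for '+' genes, BED end for '-' genes (0-based).
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    expr = read_expression(expression_path)
    records = []
    seen = set()
    for row in bed.itertuples():
        if row.name in seen:
            raise ValueError(f"duplicate gene_id {row.name} in annotation")
        seen.add(row.name)
        tss = int(row.start) if row.strand == "+" else int(row.end)
        records.append(
            GeneRecord(
                gene_id=row.name,
                chrom=row.chrom,
                tss=tss,
                strand=row.strand,
                expression=float(expr[row.name]),
            )
        )
    return records


def read_expression(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "expression"])
    return pd.Series(df.expression.values, index=df.gene_id, dtype=float)


def read_bedgraph(path) -> pd.DataFrame:
    """4-column bedGraph (chrom, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    return df


def read_binned_histone_tsv(path) -> dict[str, dict[str, np.ndarray]]:
    """Pre-binned histone counts: TSV of (gene_id, mark, 40 comma-separated counts).

    Returns ``{gene_id: {mark: counts (40,)}}``; counts are raw (not yet
    log-transformed), in transcriptional bin order.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "mark", "counts"],
                     dtype=str)
    out: dict[str, dict[str, np.ndarray]] = {}
    for row in df.itertuples():
        if row.mark not in HISTONE_MARKS:
            raise ValueError(f"unknown histone mark {row.mark!r}")
        counts = np.fromstring(row.counts, sep=",")
        if counts.size != N_BINS:
            raise ValueError(
                f"{row.gene_id}/{row.mark}: expected {N_BINS} counts, got {counts.size}"
            )
        out.setdefault(row.gene_id, {})[row.mark] = counts
    return out


def histone_matrix_from_binned(binned: dict[str, np.ndarray]) -> HistoneMatrix:
    """Assemble a :class:`HistoneMatrix` from pre-binned per-mark counts."""
    values = np.zeros((N_MARKS, N_BINS))
    for mi, mark in enumerate(HISTONE_MARKS):
        if mark in binned:
            values[mi] = np.log1p(binned[mark])
    return HistoneMatrix(values)


def read_tf_table(path) -> pd.DataFrame:
    """TSV of (gene_id, tf_name, tf_expression, n_binding_sites, binding_score)."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["gene_id", "tf_name", "tf_expression", "n_binding_sites", "binding_score"],
        dtype={"gene_id": str, "tf_name": str},
    )


def load_cell_line(directory, name: str | None = None) -> MultiOmicsDataset:
    """Read one cell line's files into a :class:`MultiOmicsDataset`.

    Expects ``genes.bed``, ``expression.tsv``, ``methylation.bedGraph``,
    ``hm_<mark>.bedGraph`` for each of the seven marks, and ``tf_table.tsv``
    in ``directory`` (the layout the synthetic generator writes).
    """
    directory = Path(directory)
    genes = read_gene_annotation(directory / "genes.bed", directory / "expression.tsv")
    catalog = tf_catalog()

    meth = read_bedgraph(directory / "methylation.bedGraph")
    meth_by_chrom = {c: g.sort_values("start") for c, g in meth.groupby("chrom")}

    hm_tracks = {}
    for mark in HISTONE_MARKS:
        df = read_bedgraph(directory / f"hm_{mark}.bedGraph")
        hm_tracks[mark] = {c: g for c, g in df.groupby("chrom")}

    tf_df = read_tf_table(directory / "tf_table.tsv")
    tf_by_gene = dict(tuple(tf_df.groupby("gene_id")))

    labels = label_genes(pd.Series({g.gene_id: g.expression for g in genes}))

    examples = []
    for gene in genes:
        reads = {}
        for mark in HISTONE_MARKS:
            chrom_df = hm_tracks[mark].get(gene.chrom)
            if chrom_df is None:
                continue
            sel = chrom_df[
                (chrom_df.end > gene.tss - WINDOW_HALF)
                & (chrom_df.start < gene.tss + WINDOW_HALF)
            ]
            reads[mark] = sel[["start", "end", "value"]].to_numpy()
        hm = bin_histone_signal(reads, gene)

        mdf = meth_by_chrom.get(gene.chrom)
        if mdf is None:
            calls = []
        else:
            sel = mdf[
                (mdf.start >= gene.tss - CPG_HALF) & (mdf.start <= gene.tss + CPG_HALF)
            ]
            calls = list(zip(sel.start.to_numpy(), sel.value.to_numpy()))
        me = extract_methylation(calls, gene)

        gdf = tf_by_gene.get(gene.gene_id)
        table = (
            []
            if gdf is None
            else list(
                zip(gdf.tf_name, gdf.tf_expression, gdf.n_binding_sites, gdf.binding_score)
            )
        )
        tf = build_tf_matrix(table, gene, catalog)

        examples.append(
            OmicsExample(gene=gene, hm=hm, me=me, tf=tf, label=int(labels[gene.gene_id]))
        )
    return MultiOmicsDataset.from_examples(examples, name=name or directory.name)
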