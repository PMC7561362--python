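"""Synthetic multi-omics cell lines with known regulatory regimes.

The generator emulates the statistical structure of promoter-centred
epigenomic data: highly expressed genes (HEG) carry a Gaussian-bump read
profile centred on the TSS for the activation-associated marks (H3K27ac,
H3K4me3, H3K9ac, and a weaker H3K4me1 enhancer signal) on top of Poisson
background, plus elevated gene-body H3K36me3; lowly expressed genes (LEG)
show flat background.  Methylation-informative genes draw promoter CpG
betas low (mean 0.1) for HEG and high (mean 0.8) for LEG.  TF-informative
genes recruit a cell-line-specific set of highly expressed activator TFs
to their promoters.  A configurable fraction of genes is *HM-ambiguous*:
their histone profile is drawn independently of the label (half look
fully activated, half silent), so histone marks alone cannot separate
them — only methylation or TF features can.

Regimes
-------
``hm``     histone marks carry the label signal; ME and TF are noise.
``me``     all genes HM-ambiguous; methylation carries the signal.
``tf``     all genes HM-ambiguous; TF features carry the signal.
``hm+me``  HM informative except for ``ambiguous_hm_fraction`` of genes;
           methylation resolves every gene; TF is noise.
``hm+tf``  as above with TF as the resolving block and ME as noise.
``mixed``  HM informative except for ``ambiguous_hm_fraction`` of genes;
           ME and TF informative throughout.

Each cell line additionally draws mild seeded nuisance variation (±30%
assay depth on the histone peaks, ±20% on methylation noise and CpG
density), emulating per-experiment sequencing-depth and assay differences:
two lines with the same configuration are similar but not statistically
identical.

Cell-line specificity, for the cross-cell-line benchmarks, comes from two
optional axes: ``primary_informative_fraction`` limits the primary ME/TF
signal to a subset of genes, and per-line *histone side-channels*
(``hm_side_channel``) let each cell line read the remaining genes' labels
through a different weak histone feature — TSS-bump bias, repressive-mark
level, enhancer-mark level, or gene-body signal.  A model trained on one
line can exploit its own side-channel but nobody else's, which is what
makes own-line models systematically the best on their own cell line.
``signal_polarity`` additionally flips the reading direction of the
distal-promoter CpG component and of the mid-expression cofactor TFs on
alternate lines.

Coordinates are synthetic: one artificial chromosome, genes spaced 10 kb,
TSS on the 100 bp bin grid.  Given a seed, generation (and file emission)
is byte-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .ingest import (
    BIN_SIZE,
    CPG_HALF,
    HISTONE_MARKS,
    N_BINS,
    N_TFS,
    WINDOW_HALF,
    GeneRecord,
    MultiOmicsDataset,
    label_genes,
    tf_catalog,
)

ACTIVATION_MARKS = ("H3K27ac", "H3K4me3", "H3K9ac")
ENHANCER_MARK = "H3K4me1"
BODY_MARK = "H3K36me3"
REPRESSIVE_MARKS = ("H3K9me3", "H3K27me3")

# weak line-specific histone side-signals: each reads out the label through
# a different histone feature, so a model transfers its side-channel
# knowledge to no other cell line
SIDE_CHANNELS = ("bump", "repressive", "enhancer", "body")

REGIMES = ("hm", "me", "tf", "hm+me", "hm+tf", "mixed")


@dataclass
class SimConfig:
    """Generator settings for one synthetic cell line."""

    seed: int
    n_genes: int = 1000
    heg_fraction: float = 0.5
    regime: str = "mixed"
    ambiguous_hm_fraction: float = 0.0
    primary_informative_fraction: float = 1.0  # genes whose ME/TF primary carries signal
    peak_amplitude: float = 40.0  # bump height, reads per 100bp bin at the TSS
    background_rate: float = 2.0  # Poisson background reads per bin
    noise_sd: float = 0.15  # spread of informative CpG betas
    me_beta_heg: float = 0.1  # informative CpG beta mean on expressed genes
    me_beta_leg: float = 0.8  # ... and on silent genes
    cpg_count_mean: float = 16.0  # Poisson mean CpGs per promoter window
    n_active_tfs: int = 12  # regime-shared activator TF set size
    tf_recruit_heg: float = 0.8  # activator candidacy probability, HEG
    tf_recruit_leg: float = 0.05  # ... and LEG
    n_polarity_tfs: int = 4  # mid-expression cofactors with line polarity
    n_private_tfs: int = 0  # extra line-private activators (own-line signal)
    me_window_frac: float = 1.0  # fraction of the promoter carrying ME signal
    signal_polarity: int = 1  # line-specific reading of the polarity component
    hm_side_channel: str | None = None  # weak line-specific histone side-signal
    tf_set_seed: int | None = None  # share activator TFs across cell lines
    cell_line: str = "sim"

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if not 0 < self.heg_fraction < 1:
            raise ValueError("heg_fraction must be in (0, 1)")
        if not 0 <= self.ambiguous_hm_fraction < 1:
            raise ValueError("ambiguous_hm_fraction must be in [0, 1)")
        if self.heg_fraction * self.n_genes < 1:
            raise ValueError("config implies fewer than one HEG gene")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if not 0 < self.me_window_frac <= 1:
            raise ValueError("me_window_frac must be in (0, 1]")
        if not 0 < self.primary_informative_fraction <= 1:
            raise ValueError("primary_informative_fraction must be in (0, 1]")
        if self.signal_polarity not in (1, -1):
            raise ValueError("signal_polarity must be +1 or -1")
        if self.hm_side_channel not in (None, *SIDE_CHANNELS):
            raise ValueError(f"hm_side_channel must be None or one of {SIDE_CHANNELS}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic cell line."""

    labels: list[int]  # +1 / -1 per gene
    driving_omics: list[list[str]]  # which blocks carry this gene's signal
    hm_ambiguous: list[bool]
    active_tfs: list[int]  # catalog columns of the activator set
    config: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


_BINS = np.arange(N_BINS)
_BUMP_SHAPE = np.exp(-((_BINS - (N_BINS - 1) / 2.0) ** 2) / (2 * 4.0**2))


def _hm_profile(rng, cfg: SimConfig, is_heg: bool, ambiguous: bool,
                informative: bool) -> np.ndarray:
    """Integer read counts (7 marks x 40 bins), transcriptional direction.

    Ambiguous genes draw their bump independently of the label: HEG can
    look silent and LEG can show an open-chromatin appearance.
    """
    lam = np.full((len(HISTONE_MARKS), N_BINS), cfg.background_rate)
    side = cfg.hm_side_channel
    if side == "repressive" and not is_heg:
        for mark in REPRESSIVE_MARKS:
            lam[HISTONE_MARKS.index(mark)] += 0.15
    elif side == "enhancer" and is_heg:
        lam[HISTONE_MARKS.index(ENHANCER_MARK)] += 0.25
    elif side == "body" and is_heg:
        lam[HISTONE_MARKS.index(BODY_MARK), N_BINS // 2 :] += 0.35
    if ambiguous:
        p_bump = 0.5
        if side == "bump":
            p_bump = 0.75 if is_heg else 0.25
        amp = cfg.peak_amplitude if rng.random() < p_bump else 0.0
    elif informative:
        amp = cfg.peak_amplitude if is_heg else 0.0
    else:
        amp = 0.0
    if amp > 0:
        for mark in ACTIVATION_MARKS:
            lam[HISTONE_MARKS.index(mark)] += amp * _BUMP_SHAPE
        lam[HISTONE_MARKS.index(ENHANCER_MARK)] += 0.5 * amp * _BUMP_SHAPE
        lam[HISTONE_MARKS.index(BODY_MARK), N_BINS // 2 :] += 0.2 * amp
    return rng.poisson(lam)


# CpGs downstream of this offset form the polarity component of the
# methylation signal: their reading direction is line-specific.  The small
# upstream-distal core keeps its direction on every line, so a model that
# resolves positions can always anchor on it
POLARITY_OFFSET = 400


def _cpg_track(rng, cfg: SimConfig, is_heg: bool, beta_means,
               signal_window: tuple[float, float]):
    """CpG offsets and betas; label signal confined to ``signal_window``.

    ``beta_means``: (heg_mean, leg_mean) of the informative betas, or None
    for a label-independent noise track.  Distal-downstream CpGs (offset
    beyond ``POLARITY_OFFSET``) read with the line's ``signal_polarity``:
    on a polarity -1 line they are hypermethylated on expressed genes.
    """
    count = rng.poisson(cfg.cpg_count_mean)
    grid = np.arange(-CPG_HALF + 1, CPG_HALF, 2)  # odd offsets, inside the window
    count = min(count, grid.size)
    offsets = np.sort(rng.choice(grid, size=count, replace=False))
    betas = rng.normal(0.5, 0.25, size=count)
    if beta_means is not None:
        in_win = (offsets >= signal_window[0]) & (offsets < signal_window[1])
        mean, other = beta_means if is_heg else beta_means[::-1]
        core = in_win & (offsets < POLARITY_OFFSET)
        distal = in_win & (offsets >= POLARITY_OFFSET)
        betas[core] = rng.normal(mean, cfg.noise_sd, size=int(core.sum()))
        distal_mean = mean if cfg.signal_polarity == 1 else other
        betas[distal] = rng.normal(distal_mean, cfg.noise_sd, size=int(distal.sum()))
    return offsets, np.round(np.clip(betas, 0.0, 1.0), 6)


def _tf_gene(rng, cfg: SimConfig, is_heg: bool, recruit_probs,
             active: np.ndarray, pol_tfs: np.ndarray, tf_expr: np.ndarray):
    """Candidate columns and their (3, c) feature block for one gene.

    ``recruit_probs``: (heg_prob, leg_prob) of each activator TF appearing
    among the gene's candidates, or None for label-independent candidacy.
    ``pol_tfs`` are the mid-expression polarity cofactors: recruited toward
    HEG on a polarity +1 line, toward LEG on a polarity -1 line.
    """
    n_bg = rng.poisson(4)
    background = rng.choice(N_TFS, size=n_bg, replace=False)
    if recruit_probs is not None:
        p_h, p_l = recruit_probs
        p = p_h if is_heg else p_l
        recruited = active[rng.random(active.size) < p]
        pp = (p_h if is_heg else p_l) if cfg.signal_polarity == 1 else (
            p_l if is_heg else p_h
        )
        pol_recruited = pol_tfs[rng.random(pol_tfs.size) < pp]
        cols = np.unique(np.concatenate([recruited, pol_recruited, background]))
    else:
        cols = np.unique(background)
    if cols.size == 0:
        return cols.astype(int), np.zeros((3, 0))
    n_sites = 1 + rng.poisson(1.0, size=cols.size)
    scores = np.round(np.clip(rng.normal(5.0, 2.0, size=cols.size), 0.1, None), 4)
    vals = np.vstack([tf_expr[cols], n_sites.astype(float), scores])
    return cols.astype(int), vals


def _simulate_raw(cfg: SimConfig) -> dict:
    """One cell line's underlying data, in transcriptional direction."""
    rng = np.random.default_rng(cfg.seed)
    tf_rng = np.random.default_rng(
        cfg.seed if cfg.tf_set_seed is None else cfg.tf_set_seed
    )
    n_pol = cfg.n_polarity_tfs
    drawn = tf_rng.choice(N_TFS, size=cfg.n_active_tfs + n_pol, replace=False)
    core = np.sort(drawn[: cfg.n_active_tfs])
    pol_tfs = np.sort(drawn[cfg.n_active_tfs :])  # mid-expression cofactors
    tf_expr = np.clip(tf_rng.normal(2.0, 1.0, size=N_TFS), 0.05, None)
    tf_expr[core] = np.clip(tf_rng.normal(8.0, 1.0, size=core.size), 0.05, None)
    tf_expr[pol_tfs] = np.clip(tf_rng.normal(5.0, 0.5, size=pol_tfs.size), 0.05, None)

    # line-private regulatory structure: extra activator TFs only this cell
    # line uses, and the sub-window of the promoter carrying the CpG signal
    if cfg.n_private_tfs:
        pool = np.setdiff1d(np.arange(N_TFS), core)
        private = np.sort(rng.choice(pool, size=cfg.n_private_tfs, replace=False))
        tf_expr[private] = np.clip(rng.normal(8.0, 1.0, size=private.size), 0.05, None)
        active = np.sort(np.concatenate([core, private]))
    else:
        active = core
    tf_expr = np.round(tf_expr, 4)
    half_span = CPG_HALF * cfg.me_window_frac
    win_lo = rng.uniform(-CPG_HALF, CPG_HALF - 2 * half_span + 1e-9)
    signal_window = (win_lo, win_lo + 2 * half_span)

    # per-line nuisance variation: seeded assay-depth / noise differences,
    # so same-configuration lines are similar but not identical
    cfg_line = replace(
        cfg,
        peak_amplitude=cfg.peak_amplitude * rng.uniform(0.7, 1.3),
        noise_sd=cfg.noise_sd * rng.uniform(0.8, 1.2),
        cpg_count_mean=cfg.cpg_count_mean * rng.uniform(0.8, 1.2),
    )

    n = cfg.n_genes
    heg = rng.random(n) < cfg.heg_fraction
    if not heg.any() or heg.all():  # degenerate draw on tiny n
        heg[0] = True
        heg[1] = False

    blocks = {"hm", "me", "tf"} if cfg.regime == "mixed" else set(cfg.regime.split("+"))
    informative = {b: b in blocks for b in ("hm", "me", "tf")}
    if informative["hm"]:
        ambiguous = rng.random(n) < cfg.ambiguous_hm_fraction
    else:  # histone marks carry no label signal anywhere
        ambiguous = np.ones(n, dtype=bool)

    beta_means = (cfg.me_beta_heg, cfg.me_beta_leg) if informative["me"] else None
    recruit_probs = (
        (cfg.tf_recruit_heg, cfg.tf_recruit_leg) if informative["tf"] else None
    )
    # a subset of genes carries no primary ME/TF signal at all; side
    # channels (and nothing else) can still read their labels
    gene_informative = rng.random(n) < cfg.primary_informative_fraction

    expr = np.where(
        heg,
        np.exp(rng.normal(2.0, 0.6, size=n)),
        np.exp(rng.normal(-2.0, 0.6, size=n)),
    )
    expr = np.round(expr, 6)

    strands = rng.choice(["+", "-"], size=n)
    genes, hm_counts, me_offs, me_betas, tf_idx, tf_vals, driving = [], [], [], [], [], [], []
    for i in range(n):
        tss = 20000 + 10000 * i
        genes.append(
            GeneRecord(
                gene_id=f"G{i:05d}", chrom="chrS", tss=tss,
                strand=str(strands[i]), expression=float(expr[i]),
            )
        )
        hm_inf = informative["hm"] and not ambiguous[i]
        hm_counts.append(_hm_profile(rng, cfg_line, heg[i], ambiguous[i], informative["hm"]))
        offs, betas = _cpg_track(
            rng, cfg_line, heg[i],
            beta_means if gene_informative[i] else None, signal_window,
        )
        me_offs.append(offs)
        me_betas.append(betas)
        cols, vals = _tf_gene(
            rng, cfg_line, heg[i],
            recruit_probs if gene_informative[i] else None,
            active, pol_tfs, tf_expr,
        )
        tf_idx.append(cols)
        tf_vals.append(vals)
        drv = []
        if hm_inf:
            drv.append("hm")
        if informative["me"]:
            drv.append("me")
        if informative["tf"]:
            drv.append("tf")
        driving.append(drv)

    truth = SimTruth(
        labels=[1 if h else -1 for h in heg],
        driving_omics=driving,
        hm_ambiguous=[bool(a) for a in ambiguous],
        active_tfs=[int(a) for a in active],
        config=asdict(cfg),
    )
    return {
        "genes": genes,
        "hm_counts": np.array(hm_counts),
        "me_offs": me_offs,
        "me_betas": me_betas,
        "tf_idx": tf_idx,
        "tf_vals": tf_vals,
        "truth": truth,
    }


def simulate_dataset(cfg: SimConfig) -> tuple[MultiOmicsDataset, SimTruth]:
    """Generate a cell line directly as an in-memory dataset.

    Labels are the per-cell-line median split of the generated expression
    values — the same rule :func:`epifusion.ingest.label_genes` applies to
    emitted files.
    """
    raw = _simulate_raw(cfg)
    genes = raw["genes"]
    labels = label_genes({g.gene_id: g.expression for g in genes})
    ds = MultiOmicsDataset(
        genes=genes,
        hm=np.log1p(raw["hm_counts"].astype(np.float64)),
        me_offsets=raw["me_offs"],
        me_betas=raw["me_betas"],
        tf_idx=raw["tf_idx"],
        tf_vals=raw["tf_vals"],
        labels=labels.loc[[g.gene_id for g in genes]].to_numpy(),
        name=cfg.cell_line,
    )
    return ds, raw["truth"]


def generate_cell_line(cfg: SimConfig, outdir) -> tuple[dict, SimTruth]:
    """Emit one synthetic cell line as the standard input files.

    Writes ``genes.bed``, ``expression.tsv``, ``methylation.bedGraph``,
    ``hm_<mark>.bedGraph`` (per mark), ``tf_table.tsv`` and ``truth.json``
    to ``outdir`` and returns the path map plus the ground truth.
    """
    raw = _simulate_raw(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = raw["genes"]
    catalog = tf_catalog()
    paths = {}

    lines = []
    for g in genes:
        start, end = (g.tss, g.tss + 1000) if g.strand == "+" else (g.tss - 1000, g.tss)
        lines.append(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}")
    paths["genes"] = outdir / "genes.bed"
    paths["genes"].write_text("\n".join(lines) + "\n")

    paths["expression"] = outdir / "expression.tsv"
    paths["expression"].write_text(
        "".join(f"{g.gene_id}\t{g.expression:.6f}\n" for g in genes)
    )

    # methylation: genomic positions, one record per CpG
    rows = []
    for g, offs, betas in zip(genes, raw["me_offs"], raw["me_betas"]):
        pos = g.tss + offs if g.strand == "+" else g.tss - offs
        for p, b in sorted(zip(pos, betas)):
            rows.append(f"{g.chrom}\t{p}\t{p + 1}\t{b:.6f}")
    paths["methylation"] = outdir / "methylation.bedGraph"
    paths["methylation"].write_text("\n".join(rows) + "\n")

    # histone marks: 100 bp tiles over each gene's window, genomic direction
    for mi, mark in enumerate(HISTONE_MARKS):
        rows = []
        for g, counts in zip(genes, raw["hm_counts"]):
            track = counts[mi] if g.strand == "+" else counts[mi][::-1]
            win_lo = g.tss - WINDOW_HALF
            for b, c in enumerate(track):
                if c > 0:
                    s = win_lo + b * BIN_SIZE
                    rows.append(f"{g.chrom}\t{s}\t{s + BIN_SIZE}\t{int(c)}")
        p = outdir / f"hm_{mark}.bedGraph"
        p.write_text("\n".join(rows) + "\n" if rows else "")
        paths[f"hm_{mark}"] = p

    rows = []
    for g, cols, vals in zip(genes, raw["tf_idx"], raw["tf_vals"]):
        for j, col in enumerate(cols):
            rows.append(
                f"{g.gene_id}\t{catalog[col]}\t{vals[0, j]:.4f}"
                f"\t{int(vals[1, j])}\t{vals[2, j]:.4f}"
            )
    paths["tf_table"] = outdir / "tf_table.tsv"
    paths["tf_table"].write_text("\n".join(rows) + "\n")

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(raw["truth"].to_json() + "\n")
    return paths, raw["truth"]


def generate_benchmark(regimes, seed: int, n_genes: int = 500,
                       outdir=None, alternate_polarity: bool = False,
                       side_channels: bool = False, **overrides):
    """A multi-cell-line benchmark: one (name, regime) pair per cell line.

    Cell lines sharing a regime share every generator parameter except the
    per-line seed (activator TF sets are tied per regime via
    ``tf_set_seed``), so same-regime transfer beats cross-regime transfer.
    Returns ``{name: (dataset, truth)}``; with ``outdir`` set, each cell
    line's files are also written to ``outdir/<name>/``.
    """
    if isinstance(regimes, dict):
        regimes = list(regimes.items())
    names = [name for name, _ in regimes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cell-line names in benchmark")
    regime_ids = {r: i for i, r in enumerate(dict.fromkeys(r for _, r in regimes))}
    within_regime: dict = {}
    out = {}
    for i, (name, regime) in enumerate(regimes):
        j = within_regime[regime] = within_regime.get(regime, -1) + 1
        cfg = SimConfig(
            seed=(seed * 100003 + 7919 * i) % (2**31),
            n_genes=n_genes,
            regime=regime,
            tf_set_seed=(seed * 100003 + regime_ids[regime]) % (2**31),
            cell_line=name,
            # with alternate_polarity, the polarity component of the signal
            # reads in opposite directions on successive same-regime lines
            signal_polarity=1 if j % 2 == 0 or not alternate_polarity else -1,
            hm_side_channel=SIDE_CHANNELS[i % 4] if side_channels else None,
            **overrides,
        )
        ds, truth = simulate_dataset(cfg)
        if outdir is not None:
            generate_cell_line(cfg, Path(outdir) / name)
        out[name] = (ds, truth)
    return out
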