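"""Synthetic study generator with a serializable truth manifest.

Emulates the paired seven-donor hepatocyte design: negative-binomial RNA-seq
counts with planted fold changes (including a strong ~12.7-fold induction
and sub-2-fold effects), duplicate Ct matrices with ceiling censoring and
planted miRNA shifts, miRNA-gene couplings realized as monotone transforms
of a gene's per-donor effect, and peak/annotation files with known promoter
overlaps.  Every random draw flows from the single manifest seed, so the
same manifest reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    TranscriptModel,
    default_catalogue,
    write_refgene,
)
from .chipseq import Peak, write_peaks
from .mirna import CtMatrix
from .rnaseq import CountMatrix

__all__ = [
    "TruthManifest",
    "default_manifest",
    "planted_gene_effects",
    "gen_counts",
    "gen_ct",
    "gen_peaks_annotation",
    "generate",
]

TREATMENT = "rifampin"
CONTROL = "vehicle"


@dataclass
class TruthManifest:
    """Ground truth and generator settings for one synthetic study.

    Planted gene folds use the signed-reciprocal display convention
    (−1.57 means a 1.57-fold reduction); miRNA shifts are treatment-minus-
    vehicle Ct differences in cycles (negative = induced); couplings are
    (mirna, gene, sign) with sign +1 for co-varying and −1 for anti-varying
    abundance.
    """

    seed: int = 0
    n_donors: int = 7
    depth: int = 1_000_000
    dispersion: float = 0.1
    donor_sigma: float = 0.3          # log2 units of shared donor baseline
    donor_effect_sigma: float = 0.2   # log2 spread of planted effects across donors
    n_background_genes: int = 150
    n_noncatalogue_genes: int = 10
    n_zero_arm_genes: int = 2
    background_cpm: tuple = (5.0, 500.0)
    planted_cpm: tuple = (2000.0, 10000.0)  # transporters are abundant in liver
    ct_replicate_sigma: float = 0.25
    ct_ceiling: float = 40.0
    n_background_mirnas: int = 300
    n_undetectable_mirnas: int = 5
    coupling_cycles_per_log2: float = 8.0
    coupling_base_shift: float = 1.5  # cycles, mean |ddCt| of a coupled miRNA
    gene_folds: dict = field(default_factory=dict)
    mirna_shifts: dict = field(default_factory=dict)
    couplings: list = field(default_factory=list)
    peak_genes: list = field(default_factory=list)
    n_unflagged_peak_genes: int = 6
    n_decoy_peaks: int = 5
    n_control_only_peaks: int = 8
    n_intergenic_unique_peaks: int = 10

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["couplings"] = [list(c) for c in self.couplings]
        d["background_cpm"] = list(self.background_cpm)
        d["planted_cpm"] = list(self.planted_cpm)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("background_cpm", "planted_cpm"):
            if key in d:
                d[key] = tuple(d[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown manifest key(s): {sorted(unknown)}")
        d["couplings"] = [tuple(c) for c in d.get("couplings", [])]
        return cls(**d)


def default_manifest(seed: int = 0) -> TruthManifest:
    """The default study conditions: 7 paired donors, deep counts, planted
    folds echoing the strongest, a moderate and a reduced transporter
    effect, and six miRNA-gene couplings (four anti-, two co-varying)."""
    return TruthManifest(
        seed=seed,
        gene_folds={
            # the clinically relevant effects
            "SLC51B": 12.67,
            "ABCC2": 1.85,
            "ABCB1": 1.72,
            "SLCO2B1": 1.73,
            "ABCC6": 1.65,
            "SLCO1B3": -1.57,
            "SLCO4C1": 1.46,
            "SLC29A1": 1.38,
            "SLC47A1": 1.37,
            "SLC22A9": -1.34,
            # further induced transporters rounding out the regulated set
            "SLC5A12": 7.0,
            "SLC2A1": 2.5,
            "SLC7A5": 3.2,
            "SLC16A3": 2.2,
            "ABCB4": 2.8,
            "SLC20A1": 1.9,
            "SLC25A4": 2.4,
            "ABCC10": 1.75,
            "SLC39A8": 2.0,
            "SLC23A2": 1.6,
            "SLC43A1": -2.1,
        },
        mirna_shifts={
            "miR-148a": -2.0,
            "miR-21": -1.5,
            "miR-192": 1.0,
        },
        couplings=[
            ("miR-92a", "SLCO1B3", -1),
            ("miR-95", "SLC47A1", -1),
            ("miR-30d#", "SLC29A1", -1),
            ("miR-202", "SLC22A9", -1),
            ("miR-660", "ABCC2", +1),
            ("miR-766", "SLC51B", +1),
        ],
        peak_genes=["ABCC2", "SLC47A1", "SLC29A1", "SLC51B"],
    )


def _rng(manifest: TruthManifest, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([manifest.seed, stream]))


def _true_ratio(display_fold: float) -> float:
    if display_fold == 0:
        raise ValueError("planted fold must be nonzero")
    return display_fold if display_fold > 0 else -1.0 / display_fold


def planted_gene_effects(manifest: TruthManifest) -> pd.DataFrame:
    """Per-donor log2 effects of the planted genes (genes x donors).

    Each gene's effect is its mean log2 fold plus a fixed, well-separated
    donor spread (a permuted symmetric grid scaled by ``donor_effect_sigma``)
    so that cross-donor rank correlations with coupled miRNAs are
    realizable.  Deterministic given the manifest seed.
    """
    rng = _rng(manifest, 1)
    n = manifest.n_donors
    grid = np.linspace(-1.5, 1.5, n)
    rows = {}
    for gene in sorted(manifest.gene_folds):
        base = np.log2(_true_ratio(manifest.gene_folds[gene]))
        rows[gene] = base + manifest.donor_effect_sigma * rng.permutation(grid)
    donors = [f"d{i + 1}" for i in range(n)]
    return pd.DataFrame(rows, index=donors).T


def gen_counts(manifest: TruthManifest) -> CountMatrix:
    """Paired count matrix with the planted fold changes.

    Counts are gamma-mixed Poisson: the negative-binomial dispersion is
    biological donor-to-donor variation, so the gamma factor with
    CV^2 = ``dispersion`` is drawn once per gene and donor and shared by
    that donor's two paired libraries, with Poisson counting noise on top.
    Marginally every count is NB(mu, dispersion); within a donor the
    biological factor cancels in the rifampin/vehicle ratio, which is what
    lets a seven-donor paired design resolve sub-2-fold effects, as the
    deep-coverage study data themselves do.

    Background genes are catalogue members with no planted effect, plus a
    few non-catalogue genes (to exercise the subset-FDR contract) and genes
    forced to zero in the vehicle arm (to exercise zero replacement).
    """
    rng = _rng(manifest, 2)
    effects = planted_gene_effects(manifest)
    donors = list(effects.columns) if len(effects) else [
        f"d{i + 1}" for i in range(manifest.n_donors)
    ]

    catalogue = default_catalogue()
    planted = list(effects.index)
    background = [
        s for s in catalogue.symbols if s not in planted
    ][: manifest.n_background_genes]
    noncat = [f"NONCAT{i + 1:03d}" for i in range(manifest.n_noncatalogue_genes)]
    zero_arm = [f"ZEROV{i + 1:02d}" for i in range(manifest.n_zero_arm_genes)]
    genes = planted + background + noncat + zero_arm

    # baseline expression: log-uniform CPM; planted transporters sit in the
    # abundant range typical of hepatic transporter mRNAs
    lo_b, hi_b = manifest.background_cpm
    lo_p, hi_p = manifest.planted_cpm
    base_cpm = 10 ** rng.uniform(np.log10(lo_b), np.log10(hi_b), size=len(genes))
    base_cpm[: len(planted)] = 10 ** rng.uniform(
        np.log10(lo_p), np.log10(hi_p), size=len(planted)
    )
    base_prop = base_cpm / 1e6
    donor_baseline = 2.0 ** rng.normal(
        0.0, manifest.donor_sigma, size=(len(genes), len(donors))
    )
    # donor-level biological dispersion, shared within each donor's pair
    donor_bio = rng.gamma(
        shape=1.0 / manifest.dispersion,
        scale=manifest.dispersion,
        size=(len(genes), len(donors)),
    )

    log2fc = np.zeros((len(genes), len(donors)))
    for i, g in enumerate(genes):
        if g in effects.index:
            log2fc[i] = effects.loc[g].to_numpy()

    mean_veh = manifest.depth * base_prop[:, None] * donor_baseline * donor_bio
    mean_rif = mean_veh * 2.0**log2fc
    zero_idx = [genes.index(g) for g in zero_arm]
    mean_veh[zero_idx, :] = 0.0
    mean_rif[zero_idx, :] = 50.0 * manifest.depth / 1e6

    cols, data, meta = [], {}, []
    for j, d in enumerate(donors):
        for treatment, mean in ((TREATMENT, mean_rif), (CONTROL, mean_veh)):
            name = f"{d}_{treatment}"
            data[name] = rng.poisson(mean[:, j])
            cols.append(name)
            meta.append({"donor": d, "treatment": treatment})
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))[cols]
    samples = pd.DataFrame(meta, index=pd.Index(cols, name="sample"))
    # the matrix holds a gene subset; the true library size is the
    # sequencing depth, recorded in the sample sheet
    samples["library_size"] = manifest.depth
    libs = pd.Series(float(manifest.depth), index=counts.columns)
    return CountMatrix(counts=counts, samples=samples, library_sizes=libs)


def gen_ct(manifest: TruthManifest) -> CtMatrix:
    """Raw technical-duplicate Ct matrix with planted shifts and couplings.

    A coupled miRNA's per-donor Ct difference is a linear (hence monotone)
    transform of its partner gene's per-donor log2 effect, applied in the
    abundance direction around a modest base shift:
    -ddCt_d = sign * (base_shift + cycles_per_log2 * (e_d - mean(e))).
    Centering keeps coupled features inside the bulk of the Ct distribution,
    where quantile normalization preserves cross-donor ordering.  Control
    small RNAs, features engineered to fail the detection rule, and
    near-ceiling undetectable features are included.
    """
    rng = _rng(manifest, 3)
    effects = planted_gene_effects(manifest)
    donors = list(effects.columns) if len(effects) else [
        f"d{i + 1}" for i in range(manifest.n_donors)
    ]
    n = len(donors)

    coupled = {m: (g, s) for m, g, s in manifest.couplings}
    planted = sorted(set(manifest.mirna_shifts) | set(coupled))
    background = [f"miR-b{i + 1:03d}" for i in range(manifest.n_background_mirnas)]
    faildet = [f"miR-dim{i + 1:02d}" for i in range(3)]  # true Ct ~39: never detected
    undet = [f"miR-nd{i + 1:02d}" for i in range(manifest.n_undetectable_mirnas)]
    controls = ["U6", "RNU44", "RNU48"]
    features = planted + background + faildet + undet + controls

    base = {f: rng.uniform(20.0, 34.0) for f in background + controls}
    # regulated features sit mid-dynamic-range so both conditions stay
    # inside the densely supported part of the array's Ct distribution
    base.update({f: rng.uniform(24.0, 30.0) for f in planted})
    base.update({f: 39.0 for f in faildet})
    base.update({f: 40.5 for f in undet})
    donor_offset = rng.normal(0.0, 0.5, size=(len(features), n))

    ddct = np.zeros((len(features), n))
    for i, f in enumerate(features):
        if f in coupled:
            gene, sign = coupled[f]
            if gene not in effects.index:
                raise ValueError(f"coupling references unplanted gene {gene!r}")
            e = effects.loc[gene].to_numpy()
            ddct[i] = -sign * (
                manifest.coupling_base_shift
                + manifest.coupling_cycles_per_log2 * (e - e.mean())
            )
            ddct[i] += manifest.mirna_shifts.get(f, 0.0)
        elif f in manifest.mirna_shifts:
            ddct[i] = manifest.mirna_shifts[f]

    cols, data, meta = [], {}, []
    for j, d in enumerate(donors):
        for treatment in (TREATMENT, CONTROL):
            for rep in (1, 2):
                name = f"{d}_{treatment}_r{rep}"
                true = np.array([base[f] for f in features]) + donor_offset[:, j]
                if treatment == TREATMENT:
                    true = true + ddct[:, j]
                obs = true + rng.normal(0.0, manifest.ct_replicate_sigma, size=len(features))
                obs[obs >= manifest.ct_ceiling] = np.nan  # censored: undetected
                obs[obs <= 0] = np.nan
                data[name] = obs
                cols.append(name)
                meta.append({"donor": d, "treatment": treatment, "replicate": rep})
    values = pd.DataFrame(data, index=pd.Index(features, name="mirna"))[cols]
    samples = pd.DataFrame(meta, index=pd.Index(cols, name="sample"))
    return CtMatrix(values=values, samples=samples, ceiling=manifest.ct_ceiling)


def gen_peaks_annotation(
    manifest: TruthManifest, flank: int = 2000
) -> tuple[list[TranscriptModel], list[Peak], list[Peak], set[str]]:
    """Synthetic chromosome with known promoter overlaps.

    Returns (transcripts, treated peaks, control peaks, genes expected to be
    hit after uniqueness filtering and promoter intersection).  Flagged
    genes receive a treated-only peak intersecting the +/-``flank`` window
    of their first isoform — one of them with the peak center beyond the
    flank while the interval still reaches in.  Decoy treated peaks overlap
    control peaks (removed by uniqueness); further control-only and
    intergenic treated-unique peaks round out both sets.
    """
    rng = _rng(manifest, 4)
    flagged = list(manifest.peak_genes)
    others = [
        g for g in sorted(manifest.gene_folds) if g not in flagged
    ] + [f"BYSTANDER{i + 1:02d}" for i in range(manifest.n_unflagged_peak_genes)]
    genes = flagged + others

    spacing, gene_len, chrom = 20_000, 5_000, "chrS"
    transcripts: list[TranscriptModel] = []
    tss_by_gene: dict[str, tuple[int, str]] = {}
    for i, g in enumerate(genes):
        start = 10_000 + i * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            TranscriptModel(f"TX{i + 1:04d}.1", g, chrom, strand, start, start + gene_len)
        )
        # a second isoform for some genes, shifted inward
        if rng.random() < 0.5:
            transcripts.append(
                TranscriptModel(
                    f"TX{i + 1:04d}.2", g, chrom, strand, start + 400, start + gene_len + 400
                )
            )
        tss1 = start + 1 if strand == "+" else start + gene_len
        tss_by_gene[g] = (tss1, strand)

    treated: list[Peak] = []
    control: list[Peak] = []
    for k, g in enumerate(flagged):
        tss, _ = tss_by_gene[g]
        width = int(rng.integers(200, 600))
        if k == 0:
            # center beyond the flank, interval reaching into the window
            center = tss + flank + 100
        else:
            center = tss + int(rng.integers(-flank + width, flank - width))
        s = center - width // 2
        treated.append(Peak(chrom, s, s + width, TREATMENT, name=f"planted_{g}"))

    # decoy treated peaks: duplicated into the control set, removed by uniqueness
    n_genes = len(genes)
    gap_mid = lambda i: 10_000 + i * spacing + gene_len + spacing // 2  # noqa: E731
    for i in range(manifest.n_decoy_peaks):
        pos = gap_mid(n_genes + i)
        treated.append(Peak(chrom, pos, pos + 300, TREATMENT, name=f"decoy{i + 1}"))
        control.append(Peak(chrom, pos + 100, pos + 400, CONTROL, name=f"ctl_over{i + 1}"))
    for i in range(manifest.n_control_only_peaks):
        pos = gap_mid(n_genes + manifest.n_decoy_peaks + i)
        control.append(Peak(chrom, pos, pos + 250, CONTROL, name=f"ctl_only{i + 1}"))
    for i in range(manifest.n_intergenic_unique_peaks):
        pos = gap_mid(n_genes + manifest.n_decoy_peaks + manifest.n_control_only_peaks + i)
        treated.append(Peak(chrom, pos, pos + 350, TREATMENT, name=f"intergenic{i + 1}"))

    treated.sort(key=lambda p: (p.chrom, p.start))
    control.sort(key=lambda p: (p.chrom, p.start))
    return transcripts, treated, control, set(flagged)


def generate(manifest: TruthManifest, outdir: str | Path | None = None) -> dict:
    """Generate every pipeline input; optionally write them to ``outdir``.

    Returns a bundle with the count matrix, raw Ct matrix, transcripts,
    treated/control peak sets, the expected promoter-hit genes, and the
    manifest itself.
    """
    counts = gen_counts(manifest)
    ct = gen_ct(manifest)
    transcripts, treated, control, hit_genes = gen_peaks_annotation(manifest)
    bundle = {
        "counts": counts,
        "ct": ct,
        "transcripts": transcripts,
        "treated_peaks": treated,
        "control_peaks": control,
        "expected_hit_genes": hit_genes,
        "gene_effects": planted_gene_effects(manifest),
        "manifest": manifest,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts.counts.to_csv(outdir / "counts.tsv", sep="\t")
        counts.samples.to_csv(outdir / "count_samples.tsv", sep="\t")
        ct.values.to_csv(outdir / "ct.csv")
        ct.samples.to_csv(outdir / "ct_samples.tsv", sep="\t")
        write_refgene(transcripts, outdir / "annotation.tsv")
        write_peaks(treated, outdir / "treated.bed")
        write_peaks(control, outdir / "control.bed")
        default_catalogue().frame.to_csv(outdir / "catalogue.tsv", sep="\t", index=False)
        manifest.to_yaml(outdir / "truth.yaml")
    return bundle
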