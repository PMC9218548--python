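"""Seeded synthetic dataset with planted ground truth.

Emulates the seasonal-form wing study design: 2 forms x 4 stages x 4
replicates of gene and miRNA counts (negative binomial), junction counts for
alternative-splicing events, 3'UTR and mature-miRNA sequences, and a planted
regulatory layer in which each miRNA->gene pair is realized twice over —
as a perfect-complement binding site embedded in the gene's 3'UTR, and as
negative expression coupling between the miRNA and the gene.

Everything downstream of this module treats the generated files/objects
exactly like real data; the :class:`PlantedTruth` object is only consulted
when scoring recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import FORMS, STAGES, SampleDesign, default_design
from .matrix import ExpressionMatrix
from .splicing import SpliceEvent

RNA = "ACGU"
DNA = "ACGT"
_COMPLEMENT_RNA = str.maketrans("ACGU", "UGCA")

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_COMPLEMENT_RNA)[::-1]


@dataclass
class GeneratorConfig:
    """Tunable knobs of the synthetic study.

    Defaults emulate the study conditions: stage-specific DE fractions of
    10% (genes) and 15% (miRNAs) with |log2FC| in {1, 1.5, 2}, 150 planted
    regulatory pairs with repression strength beta = 2, NB dispersion
    log-uniform in [0.01, 0.5], and one dropped outlier library.
    """

    n_genes: int = 2000
    n_mirnas: int = 100
    n_pairs: int = 150
    de_fraction_genes: float = 0.10
    de_fraction_mirnas: float = 0.15
    effect_sizes: tuple[float, ...] = (1.0, 1.5, 2.0)
    beta: float = 2.0
    utr_length: tuple[int, int] = (300, 600)
    gene_mean_range: tuple[float, float] = (20.0, 2000.0)
    mirna_mean_range: tuple[float, float] = (50.0, 5000.0)
    dispersion_range: tuple[float, float] = (0.01, 0.5)
    library_factor_range: tuple[float, float] = (0.75, 1.35)
    mature_length: tuple[int, int] = (17, 25)
    n_events: int = 300
    ds_event_fraction: float = 0.2
    dpsi_range: tuple[float, float] = (0.2, 0.6)
    junction_depth: float = 200.0
    n_eyespot: int = 120
    eyespot_up_fraction: float = 0.58
    contig_flank: int = 50

    def validate(self) -> None:
        if self.n_pairs > self.n_genes * self.n_mirnas:
            raise ValueError("n_pairs exceeds n_genes * n_mirnas")
        if self.n_pairs > self.n_genes:
            raise ValueError("n_pairs exceeds n_genes (one site per gene)")
        if self.utr_length[0] < 30:
            raise ValueError("UTRs must be at least 30 nt")
        if self.utr_length[0] < self.mature_length[1] + 60:
            raise ValueError("UTRs too short to embed a site away from edges")
        if not 0 < self.junction_depth:
            raise ValueError("junction depth must be positive")


@dataclass
class GeneFeature:
    id: str
    baseline: float
    dispersion: float


@dataclass
class MirnaFeature:
    id: str
    mature: str  # RNA alphabet, 5'->3'
    baseline: float
    dispersion: float


@dataclass
class RegulatoryPair:
    mirna: str
    gene: str
    beta: float
    site_start: int  # 0-based start of the embedded site in the gene 3'UTR
    site_end: int  # half-open end


@dataclass
class EventSpec:
    id: str
    gene: str
    etype: str
    li: int
    ls: int
    psi: dict  # form -> true PSI


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic dataset; pure function of (config, seed)."""

    config: GeneratorConfig
    seed: int
    genes: list
    mirnas: list
    de_effects: dict  # (feature id, stage) -> planted log2FC (WS over DS)
    pairs: list
    events: list
    utrs: dict  # gene id -> 3'UTR (DNA, 5'->3')
    contigs: dict  # gene id -> contig sequence embedding the UTR
    utr_start: int  # 0-based start of the UTR within every contig
    eyespot: dict  # gene id -> "up" | "down" (surrogate labeled list)

    @property
    def regulatory_pairs(self) -> set:
        return {(p.mirna, p.gene) for p in self.pairs}

    def splice_effects(self) -> dict:
        return {(e.id, form): e.psi[form] for e in self.events for form in FORMS}

    def to_dict(self) -> dict:
        d = {
            "config": asdict(self.config),
            "seed": self.seed,
            "genes": [asdict(g) for g in self.genes],
            "mirnas": [asdict(m) for m in self.mirnas],
            "de_effects": [[f, s, v] for (f, s), v in sorted(self.de_effects.items())],
            "pairs": [asdict(p) for p in self.pairs],
            "events": [asdict(e) for e in self.events],
            "utrs": self.utrs,
            "contigs": self.contigs,
            "utr_start": self.utr_start,
            "eyespot": self.eyespot,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        cfg = GeneratorConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in d["config"].items()
        })
        return cls(
            config=cfg,
            seed=d["seed"],
            genes=[GeneFeature(**g) for g in d["genes"]],
            mirnas=[MirnaFeature(**m) for m in d["mirnas"]],
            de_effects={(f, s): v for f, s, v in d["de_effects"]},
            pairs=[RegulatoryPair(**p) for p in d["pairs"]],
            events=[EventSpec(**e) for e in d["events"]],
            utrs=d["utrs"],
            contigs=d["contigs"],
            utr_start=d["utr_start"],
            eyespot=d["eyespot"],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlantedTruth):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_truth(config: GeneratorConfig | None = None, seed: int = 0) -> PlantedTruth:
    """Draw a :class:`PlantedTruth` — deterministic given (config, seed).

    Every regulatory pair's gene receives one embedded site equal to the
    reverse complement of the mature miRNA positions 2..end followed by an A
    (a canonical 8mer with perfect 3' pairing), at a recorded UTR position.
    The miRNA and its target gene are planted differentially expressed with
    opposite signs at a shared nonempty subset of stages.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))

    width = len(str(config.n_genes))
    genes = [
        GeneFeature(
            id=f"g{i + 1:0{width}d}",
            baseline=float(b),
            dispersion=float(d),
        )
        for i, (b, d) in enumerate(
            zip(
                _log_uniform(rng, *config.gene_mean_range, size=config.n_genes),
                _log_uniform(rng, *config.dispersion_range, size=config.n_genes),
            )
        )
    ]
    mwidth = len(str(config.n_mirnas))
    mirnas = []
    for j in range(config.n_mirnas):
        length = int(rng.integers(config.mature_length[0], config.mature_length[1] + 1))
        first = "U" if rng.random() < 0.6 else str(rng.choice(list(RNA)))
        mature = first + _random_seq(rng, RNA, length - 1)
        mirnas.append(
            MirnaFeature(
                id=f"mir{j + 1:0{mwidth}d}",
                mature=mature,
                baseline=float(_log_uniform(rng, *config.mirna_mean_range)),
                dispersion=float(_log_uniform(rng, *config.dispersion_range)),
            )
        )

    # stage-specific random DE effects
    de_effects: dict = {}
    for stage in STAGES:
        n_de_g = int(round(config.de_fraction_genes * config.n_genes))
        for i in rng.choice(config.n_genes, size=n_de_g, replace=False):
            lfc = float(rng.choice(config.effect_sizes)) * float(rng.choice([-1.0, 1.0]))
            de_effects[(genes[i].id, stage)] = lfc
        n_de_m = int(round(config.de_fraction_mirnas * config.n_mirnas))
        for j in rng.choice(config.n_mirnas, size=n_de_m, replace=False):
            lfc = float(rng.choice(config.effect_sizes)) * float(rng.choice([-1.0, 1.0]))
            de_effects[(mirnas[j].id, stage)] = lfc

    # regulatory pairs: distinct genes, miRNAs may target several genes
    pair_gene_idx = rng.choice(config.n_genes, size=config.n_pairs, replace=False)
    pair_mir_idx = rng.choice(config.n_mirnas, size=config.n_pairs, replace=True)
    mir_profile: dict = {}
    for j in sorted(set(int(j) for j in pair_mir_idx)):
        mid = mirnas[j].id
        stages = [s for s in STAGES if rng.random() < 0.5]
        if not stages:
            stages = [str(rng.choice(STAGES))]
        sign = float(rng.choice([-1.0, 1.0]))
        lfcs = {s: sign * float(rng.choice(config.effect_sizes)) for s in stages}
        mir_profile[mid] = (sign, lfcs)
        for (f, s) in [k for k in de_effects if k[0] == mid]:
            del de_effects[(f, s)]
        for s, v in lfcs.items():
            de_effects[(mid, s)] = v

    pairs: list[RegulatoryPair] = []
    for i, j in zip(pair_gene_idx, pair_mir_idx):
        gid, mid = genes[int(i)].id, mirnas[int(j)].id
        sign, lfcs = mir_profile[mid]
        for (f, s) in [k for k in de_effects if k[0] == gid]:
            del de_effects[(f, s)]
        for s in lfcs:
            de_effects[(gid, s)] = -sign * float(rng.choice(config.effect_sizes))
        pairs.append(RegulatoryPair(mirna=mid, gene=gid, beta=config.beta,
                                    site_start=-1, site_end=-1))

    # 3'UTRs with one embedded perfect-complement site per regulated gene
    mature_by_id = {m.id: m.mature for m in mirnas}
    utrs: dict = {}
    lengths = rng.integers(config.utr_length[0], config.utr_length[1] + 1,
                           size=config.n_genes)
    for g, L in zip(genes, lengths):
        utrs[g.id] = _random_seq(rng, DNA, int(L))
    for p in pairs:
        mature = mature_by_id[p.mirna]
        site_rna = reverse_complement_rna(mature[1:]) + "A"
        site = site_rna.replace("U", "T")
        utr = utrs[p.gene]
        pos = int(rng.integers(30, len(utr) - len(site) - 30))
        utrs[p.gene] = utr[:pos] + site + utr[pos + len(site):]
        p.site_start, p.site_end = pos, pos + len(site)

    # contigs embedding each UTR, for GFF3 cross-file consistency
    flank = config.contig_flank
    contigs = {
        gid: _random_seq(rng, DNA, flank) + utr + _random_seq(rng, DNA, flank)
        for gid, utr in utrs.items()
    }

    # splice events: form-specific true PSI, a fraction with a planted shift
    events: list[EventSpec] = []
    ewidth = len(str(config.n_events))
    for k in range(config.n_events):
        gene = genes[int(rng.integers(config.n_genes))].id
        etype = str(rng.choice(EVENT_TYPES))
        li = int(rng.integers(1, 4))
        ls = int(rng.integers(1, 4))
        if rng.random() < config.ds_event_fraction:
            delta = float(rng.uniform(*config.dpsi_range)) * float(rng.choice([-1.0, 1.0]))
            lo = max(0.02, 0.02 - delta)
            hi = min(0.98, 0.98 - delta)
            psi_ws = float(rng.uniform(lo, hi))
            psi_ds = psi_ws + delta
        else:
            psi_ws = psi_ds = float(rng.uniform(0.15, 0.85))
        events.append(
            EventSpec(
                id=f"e{k + 1:0{ewidth}d}",
                gene=gene,
                etype=etype,
                li=li,
                ls=ls,
                psi={"WS": psi_ws, "DS": psi_ds},
            )
        )

    # surrogate eyespot-associated gene list with direction labels
    n_eye = min(config.n_eyespot, config.n_genes)
    eye_idx = rng.choice(config.n_genes, size=n_eye, replace=False)
    n_up = int(round(config.eyespot_up_fraction * n_eye))
    eyespot = {
        genes[int(i)].id: ("up" if rank < n_up else "down")
        for rank, i in enumerate(eye_idx)
    }

    return PlantedTruth(
        config=config,
        seed=int(seed),
        genes=genes,
        mirnas=mirnas,
        de_effects=de_effects,
        pairs=pairs,
        events=events,
        utrs=utrs,
        contigs=contigs,
        utr_start=flank,
        eyespot=eyespot,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance mu + alpha * mu^2."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _form_shift(lfc: float, form: str) -> float:
    """Half the planted log2FC, signed so that WS/DS differ by the full lfc."""
    return 0.5 * lfc if form == "WS" else -0.5 * lfc


def simulate_counts(
    truth: PlantedTruth, design: SampleDesign | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Simulate gene and miRNA count matrices under the planted truth.

    Per sample, a feature's NB mean is baseline x 2^(+-lfc/2 by form at the
    sample's stage) x library factor. For a regulated gene the mean is
    additionally multiplied by 2^(-beta * z) where z is that sample's
    standardized miRNA deviation from baseline (log2 normalized counts),
    which creates negative miRNA-gene cross-correlation.

    Samples listed in ``design.dropped`` are absent from both emitted
    matrices.
    """
    design = design or default_design()
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 23]))
    samples = design.samples
    ids = [s.id for s in samples]

    lo, hi = cfg.library_factor_range
    lib_gene = _log_uniform(rng, lo, hi, size=len(samples))
    lib_mir = _log_uniform(rng, lo, hi, size=len(samples))

    # miRNAs first: gene coupling needs their realized counts
    mir_counts = np.zeros((len(truth.mirnas), len(samples)), dtype=np.int64)
    for i, m in enumerate(truth.mirnas):
        mu = np.array(
            [
                m.baseline
                * 2.0 ** _form_shift(truth.de_effects.get((m.id, s.stage), 0.0), s.form)
                * lib_mir[j]
                for j, s in enumerate(samples)
            ]
        )
        mir_counts[i] = _nb_draw(rng, mu, m.dispersion)

    mir_index = {m.id: i for i, m in enumerate(truth.mirnas)}
    zscores: dict = {}
    for p in truth.pairs:
        if p.mirna in zscores:
            continue
        logn = np.log2(mir_counts[mir_index[p.mirna]] / lib_mir + 1.0)
        sd = logn.std()
        zscores[p.mirna] = (logn - logn.mean()) / sd if sd > 0 else np.zeros_like(logn)

    coupling = {}  # gene id -> summed beta * z across its regulators
    for p in truth.pairs:
        coupling.setdefault(p.gene, np.zeros(len(samples)))
        coupling[p.gene] = coupling[p.gene] + p.beta * zscores[p.mirna]

    gene_counts = np.zeros((len(truth.genes), len(samples)), dtype=np.int64)
    for i, g in enumerate(truth.genes):
        shift = np.array(
            [
                _form_shift(truth.de_effects.get((g.id, s.stage), 0.0), s.form)
                for s in samples
            ]
        )
        mu = g.baseline * 2.0 ** shift * lib_gene
        if g.id in coupling:
            mu = mu * 2.0 ** (-coupling[g.id])
        gene_counts[i] = _nb_draw(rng, mu, g.dispersion)

    meta = pd.DataFrame(
        {"form": [s.form for s in samples], "stage": [s.stage for s in samples],
         "replicate": [s.replicate for s in samples]},
        index=pd.Index(ids, name="sample"),
    )
    keep = design.ids(analyzed_only=True)
    gdf = pd.DataFrame(gene_counts, index=[g.id for g in truth.genes], columns=ids)[keep]
    mdf = pd.DataFrame(mir_counts, index=[m.id for m in truth.mirnas], columns=ids)[keep]
    return (
        ExpressionMatrix(gdf, meta.loc[keep], kind="gene"),
        ExpressionMatrix(mdf, meta.loc[keep], kind="miRNA"),
    )


def simulate_junctions(
    truth: PlantedTruth,
    design: SampleDesign | None = None,
    depth: float | None = None,
) -> list[SpliceEvent]:
    """Simulate per-sample inclusion/skipping junction counts.

    Inclusion counts are Binomial(total, q) with q the planted PSI pushed
    through the effective-length weighting, so the length-corrected PSI
    estimator is unbiased for the planted PSI; totals are Poisson(depth).
    """
    design = design or default_design()
    depth = float(truth.config.junction_depth if depth is None else depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 37]))
    out: list[SpliceEvent] = []
    analyzed = design.analyzed
    for e in truth.events:
        inc: dict = {}
        skp: dict = {}
        for s in analyzed:
            psi = e.psi[s.form]
            q = psi * e.li / (psi * e.li + (1.0 - psi) * e.ls)
            total = int(rng.poisson(depth))
            i = int(rng.binomial(total, q)) if total > 0 else 0
            inc[s.id] = i
            skp[s.id] = total - i
        out.append(
            SpliceEvent(
                event_id=e.id, gene_id=e.gene, etype=e.etype,
                li=e.li, ls=e.ls, inclusion=inc, skipping=skp,
            )
        )
    return out
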