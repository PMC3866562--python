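"""Seeded synthetic-data generator with planted ground truth.

Emulates every input the pipeline consumes: a genome with non-overlapping
multi-exon genes (intron lengths drawn from a short/long log-normal
mixture), tiered binding-interval datasets from two techniques with
planted true sites, TF interval-set pairs with a controlled shared-site
fraction, two-colour expression data in which the majority of genes
change but an invariant subset does not, and sequences with PWM words
planted at a controlled rate.

One top-level seed fans out to per-stage child seeds (numpy SeedSequence
spawn keys), so each stage can be regenerated independently and the full
run is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .expression import ArrayChannelData
from .genome import GeneModel, GenomeAnnotation, Interval, IntervalSet, SeqSpace
from .motif import PWMCounts, PWMModel, build_pwm, sample_word

_STAGE_KEYS = {
    "annotation": 0,
    "binding": 1,
    "tf_pair": 2,
    "expression": 3,
    "sequences": 4,
    "terms": 5,
}


@dataclass
class SimConfig:
    """Study conditions for all synthetic stages.

    Binding-tier sensitivities and false-positive loads give the stringent
    tier high precision / moderate recall and the permissive tier high
    recall / low precision, mimicking 1% vs 25% FDR calls.  The expression
    block places ~65% of genes at +-shift (a regime where global centring
    fails) with a dominant down direction.
    """

    seed: int = 1
    # genome / annotation
    n_chroms: int = 4
    chrom_len: int = 5_000_000
    n_genes: int = 2000
    intron_short_mu: float = 4.8   # natural-log scale
    intron_long_mu: float = 8.5
    intron_short_sigma: float = 1.0
    intron_long_sigma: float = 0.7
    intron_long_frac: float = 0.2
    exon_len_mu: float = 5.7
    exon_len_sigma: float = 0.6
    max_exons: int = 10
    min_gap: int = 200
    # binding evidence
    n_true_sites: int = 500
    sens_high: float = 0.7
    sens_low: float = 0.95
    fp_high: int = 50
    fp_low: int = 500
    len_min: int = 200
    len_max: int = 800
    tss_site_frac: float = 0.25    # fraction of true sites placed near a TSS
    tss_site_window: int = 500
    detect_jitter: int = 50
    # TF pair
    n_tf_intervals: int = 2500
    tf_pair_rho: float = 0.5
    tf_jitter: int = 100
    # expression
    n_arrays: int = 4
    dye_swaps: tuple[bool, ...] = (False, False, True, True)
    invariant_frac: float = 0.35
    de_shift: float = 2.0
    de_down_frac: float = 0.9
    noise_sd: float = 0.3
    dye_bias_amp: float = 0.3
    a_mean: float = 10.0
    a_sd: float = 2.0
    # motif sequences
    motif_plant_rate: float = 0.8
    n_motif_seqs: int = 1000
    motif_seq_len: int = 500

    def __post_init__(self) -> None:
        for name in ("sens_high", "sens_low", "tss_site_frac", "tf_pair_rho",
                     "invariant_frac", "de_down_frac", "motif_plant_rate",
                     "intron_long_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_len", "n_genes", "n_true_sites",
                     "fp_high", "fp_low", "n_tf_intervals", "n_arrays",
                     "n_motif_seqs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGE_KEYS[stage],))
        )


@dataclass
class SimTruth:
    """Planted ground truth; stages fill the fields they own."""

    sites: list[Interval] = field(default_factory=list)
    detected: dict[str, np.ndarray] = field(default_factory=dict)  # dataset label -> bool per site
    shared_mask: Optional[np.ndarray] = None          # TF pair: set-2 intervals copied from set-1
    invariant_genes: set[str] = field(default_factory=set)
    de_direction: dict[str, str] = field(default_factory=dict)  # gene -> up|down
    motif_offsets: dict[str, Optional[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def _intron_lengths(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    is_long = rng.random(n) < cfg.intron_long_frac
    mu = np.where(is_long, cfg.intron_long_mu, cfg.intron_short_mu)
    sigma = np.where(is_long, cfg.intron_long_sigma, cfg.intron_short_sigma)
    lens = np.exp(rng.normal(mu, sigma))
    return np.maximum(lens.astype(np.int64), 30)


def simulate_annotation(cfg: SimConfig) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Non-overlapping genes with 1-10 exons on a random ACGT genome."""
    rng = cfg.rng("annotation")
    space = SeqSpace({f"chr{i + 1}": cfg.chrom_len for i in range(cfg.n_chroms)})
    genes: list[GeneModel] = []
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    gi = 0
    for ci, chrom in enumerate(space.chroms):
        g = per_chrom[ci]
        structures = []
        for _ in range(g):
            n_ex = int(rng.integers(1, cfg.max_exons + 1))
            ex_lens = np.maximum(
                np.exp(rng.normal(cfg.exon_len_mu, cfg.exon_len_sigma, n_ex)).astype(np.int64),
                20,
            )
            in_lens = _intron_lengths(cfg, rng, n_ex - 1)
            structures.append((ex_lens, in_lens))
        totals = [int(e.sum() + i_.sum()) for e, i_ in structures]
        needed = sum(totals) + (g + 1) * cfg.min_gap
        if needed > cfg.chrom_len:
            raise ValueError(
                f"cannot pack {g} genes ({needed} bp incl. gaps) into {chrom} "
                f"({cfg.chrom_len} bp)"
            )
        extra = cfg.chrom_len - needed
        gaps = cfg.min_gap + rng.multinomial(extra, np.full(g + 1, 1.0 / (g + 1)))
        pos = 0
        for (ex_lens, in_lens), gap in zip(structures, gaps[:-1]):
            pos += int(gap)
            start = pos
            exons = []
            for j, el in enumerate(ex_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if j < len(in_lens):
                    pos += int(in_lens[j])
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"g{gi:05d}",
                    chrom=chrom,
                    start=start,
                    end=pos,
                    strand="+" if rng.random() < 0.5 else "-",
                    transcripts=[exons],
                )
            )
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {
        chrom: lut[rng.integers(0, 4, size=cfg.chrom_len, dtype=np.int64)]
        .tobytes()
        .decode("ascii")
        for chrom in space.chroms
    }
    return GenomeAnnotation(seqspace=space, genes=genes), sequences


# ---------------------------------------------------------------------------


def _uniform_intervals(
    rng: np.random.Generator, space: SeqSpace, n: int, len_min: int, len_max: int,
    prefix: str,
) -> list[Interval]:
    chroms = space.chroms
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        ln = int(rng.integers(len_min, len_max + 1))
        start = int(rng.integers(0, space[chrom] - ln + 1))
        out.append(Interval(chrom, start, start + ln, id=f"{prefix}{i:05d}"))
    return out


def simulate_binding_evidence(
    cfg: SimConfig, ann: GenomeAnnotation
) -> tuple[list[IntervalSet], SimTruth]:
    """Two techniques x two tiers of binding calls around planted true sites.

    A fraction of true sites sits near a TSS; per technique a site is
    detected at the permissive tier with probability sens_low and (nested)
    at the stringent tier with probability sens_high, its reported span
    jittered per technique.  Tier-specific false positives are placed
    uniformly, the permissive tier's FP set containing the stringent
    tier's.
    """
    rng = cfg.rng("binding")
    space = ann.seqspace
    chroms = space.chroms
    n = cfg.n_true_sites
    sites: list[Interval] = []
    genes = ann.genes
    for i in range(n):
        ln = int(rng.integers(cfg.len_min, cfg.len_max + 1))
        near_tss = genes and rng.random() < cfg.tss_site_frac
        if near_tss:
            g = genes[int(rng.integers(0, len(genes)))]
            centre = g.start + int(rng.integers(-cfg.tss_site_window, cfg.tss_site_window + 1))
            chrom = g.chrom
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            centre = int(rng.integers(0, space[chrom]))
        start = max(0, min(centre - ln // 2, space[chrom] - ln))
        sites.append(Interval(chrom, start, start + ln, id=f"site{i:05d}"))

    truth = SimTruth(sites=sites)
    datasets: list[IntervalSet] = []
    for technique in ("damid", "chip"):
        u = rng.random(n)
        jitter = rng.integers(-cfg.detect_jitter, cfg.detect_jitter + 1, size=n)
        det_high = u < cfg.sens_high
        det_low = u < cfg.sens_low
        observed = []
        for i, site in enumerate(sites):
            s = int(np.clip(site.start + jitter[i], 0, space[site.chrom] - site.length))
            observed.append(Interval(site.chrom, s, s + site.length, id=f"{technique}_{site.id}"))
        fp_low = _uniform_intervals(
            rng, space, cfg.fp_low, cfg.len_min, cfg.len_max, prefix=f"{technique}_fp"
        )
        fp_high = fp_low[: cfg.fp_high]
        for tier, det, fps in (
            (1.0, det_high, fp_high),
            (25.0, det_low, fp_low),
        ):
            label = f"{technique}_fdr{tier:g}"
            ivs = [observed[i] for i in range(n) if det[i]] + fps
            ivs.sort(key=lambda iv: (iv.chrom, iv.start))
            datasets.append(
                IntervalSet(
                    label=label, intervals=ivs, technique=technique,
                    fdr_tier=tier, seqspace=space,
                )
            )
            truth.detected[label] = det.copy()
    return datasets, truth


# ---------------------------------------------------------------------------


def simulate_tf_pair(
    cfg: SimConfig, space: SeqSpace, rho: Optional[float] = None,
    n: Optional[int] = None, rng: Optional[np.random.Generator] = None,
) -> tuple[IntervalSet, IntervalSet, SimTruth]:
    """Two TF interval sets where a fraction rho of set-2 intervals is
    copied (with +-jitter) from set-1 and the remainder placed uniformly."""
    if rng is None:
        rng = cfg.rng("tf_pair")
    if rho is None:
        rho = cfg.tf_pair_rho
    if n is None:
        n = cfg.n_tf_intervals
    a = _uniform_intervals(rng, space, n, cfg.len_min, cfg.len_max, prefix="tfA_")
    n_shared = int(round(rho * n))
    shared = np.zeros(n, dtype=bool)
    shared[:n_shared] = True
    sources = rng.choice(n, size=n_shared, replace=n_shared > n)
    b: list[Interval] = []
    for i in range(n_shared):
        src = a[int(sources[i])]
        shift = int(rng.integers(-cfg.tf_jitter, cfg.tf_jitter + 1))
        s = int(np.clip(src.start + shift, 0, space[src.chrom] - src.length))
        b.append(Interval(src.chrom, s, s + src.length, id=f"tfB_{i:05d}"))
    b.extend(
        _uniform_intervals(rng, space, n - n_shared, cfg.len_min, cfg.len_max, prefix="tfB_u")
    )
    set_a = IntervalSet("tfA", a, technique="chip", fdr_tier=1.0, seqspace=space)
    set_b = IntervalSet("tfB", b, technique="chip", fdr_tier=1.0, seqspace=space)
    return set_a, set_b, SimTruth(shared_mask=shared)


# ---------------------------------------------------------------------------


def simulate_expression(
    cfg: SimConfig,
    genes: GenomeAnnotation | Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[ArrayChannelData], SimTruth]:
    """Two-colour arrays where the majority of genes change expression.

    Invariant genes have true M = 0; the rest sit at +-de_shift with a
    configured direction mix.  Each array adds a smooth intensity-dependent
    dye-bias curve plus Gaussian noise; dye-swapped arrays are emitted with
    the sign of M flipped.
    """
    if rng is None:
        rng = cfg.rng("expression")
    if isinstance(genes, GenomeAnnotation):
        gene_ids = np.array(sorted(g.gene_id for g in genes.genes))
    else:
        gene_ids = np.asarray(list(genes))
    G = len(gene_ids)
    n_inv = int(round(cfg.invariant_frac * G))
    inv_idx = rng.choice(G, size=n_inv, replace=False)
    invariant = np.zeros(G, dtype=bool)
    invariant[inv_idx] = True
    down = rng.random(G) < cfg.de_down_frac
    true_m = np.where(invariant, 0.0, np.where(down, -cfg.de_shift, cfg.de_shift))
    a_base = rng.normal(cfg.a_mean, cfg.a_sd, G)
    a_lo, a_hi = a_base.min(), a_base.max()

    arrays: list[ArrayChannelData] = []
    swaps = list(cfg.dye_swaps)
    if len(swaps) < cfg.n_arrays:
        swaps = (swaps * cfg.n_arrays)[: cfg.n_arrays]
    for j in range(cfg.n_arrays):
        phase = rng.uniform(0, 2 * np.pi)
        amp = cfg.dye_bias_amp * rng.uniform(0.5, 1.0)
        z = (a_base - a_lo) / max(a_hi - a_lo, 1e-9)
        bias = amp * np.sin(np.pi * z + phase)
        m_oriented = true_m + bias + rng.normal(0.0, cfg.noise_sd, G)
        m_emitted = -m_oriented if swaps[j] else m_oriented
        a_obs = a_base + rng.normal(0.0, 0.1, G)
        arrays.append(
            ArrayChannelData(
                array_id=f"a{j + 1}",
                genes=gene_ids,
                M=m_emitted,
                A=a_obs,
                dye_swapped=bool(swaps[j]),
            )
        )
    truth = SimTruth(
        invariant_genes={str(g) for g in gene_ids[invariant]},
        de_direction={
            str(g): ("down" if d else "up")
            for g, d, inv in zip(gene_ids, down, invariant)
            if not inv
        },
    )
    return arrays, truth


# ---------------------------------------------------------------------------


def default_pwm_counts() -> PWMCounts:
    """A sharp 8-bp Sox-like (CAACAATG) count matrix used as the default
    synthetic motif.  Deliberately high-information so that a word sampled
    from it almost surely clears the retrieval threshold, keeping the
    planted signal separable from background matches."""
    consensus = "CAACAATG"
    counts = np.full((4, len(consensus)), 1.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 300.0
    return PWMCounts(counts)


def simulate_sequences(
    cfg: SimConfig,
    pwm: Optional[PWMModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, str], SimTruth]:
    """Random background sequences with PWM-sampled words planted in a
    ``motif_plant_rate`` fraction; planted offsets are recorded (None for
    unplanted sequences)."""
    if rng is None:
        rng = cfg.rng("sequences")
    if pwm is None:
        pwm = build_pwm(default_pwm_counts())
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, str] = {}
    truth = SimTruth()
    W = pwm.width
    for i in range(cfg.n_motif_seqs):
        name = f"seq{i:05d}"
        codes = rng.integers(0, 4, size=cfg.motif_seq_len, dtype=np.int64)
        seq = lut[codes].tobytes().decode("ascii")
        if rng.random() < cfg.motif_plant_rate:
            off = int(rng.integers(0, cfg.motif_seq_len - W + 1))
            word = sample_word(pwm, rng)
            seq = seq[:off] + word + seq[off + W :]
            truth.motif_offsets[name] = off
        else:
            truth.motif_offsets[name] = None
        seqs[name] = seq
    return seqs, truth


# ---------------------------------------------------------------------------


def simulate_term_map(
    cfg: SimConfig,
    gene_ids: Sequence[str],
    focus_genes: set[str],
    n_terms: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, set[str]]:
    """A small term-to-gene map: one term concentrated in ``focus_genes``
    plus random terms, for exercising enrichment end-to-end."""
    if rng is None:
        rng = cfg.rng("terms")
    gene_ids = list(gene_ids)
    terms: dict[str, set[str]] = {}
    focus = sorted(focus_genes)
    if focus:
        k = max(5, len(focus) // 4)
        pick = rng.choice(len(focus), size=min(k, len(focus)), replace=False)
        terms["term_focus"] = {focus[i] for i in pick}
    for t in range(n_terms):
        size = int(rng.integers(20, 201))
        pick = rng.choice(len(gene_ids), size=min(size, len(gene_ids)), replace=False)
        terms[f"term_{t:02d}"] = {gene_ids[i] for i in pick}
    return terms
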