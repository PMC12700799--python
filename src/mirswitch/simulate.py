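"""Synthetic hairpin catalogs and genotype-dependent datasets with ground truth.

The generator emulates the biogenesis/loading mechanism the analysis assumes:

* WT / HetKO Dicer processes each precursor into a duplex; AGO loads one
  strand with probability given by the logistic asymmetry model
  (:mod:`mirswitch.strands`).  Loaded strands are protected (abundance
  multiplier ``rho``), unloaded strands decay (survival ``delta``).
* The RNase IIIb hotspot mutant (HM) nicks only the 3p arm: a fraction
  ``1 - epsilon`` of precursors yield a 5p+loop intermediate plus a free 3p
  strand (loaded on its own score; the 5p+loop strand cannot load), and a
  residual fraction ``epsilon`` is processed into a normal duplex.
* The RNase IIIa mutant nicks only the 5p arm: 3p+loop plus a free 5p strand
  whose 3' end is non-covalently occluded by the loop (factor ``kappa``).
* 5p+loop (and 3p+loop) intermediates are detectable with per-hairpin
  probability ``s_int`` (Beta-distributed: some intermediates are stable and
  library-visible, others are not).
* Sequencing counts are negative binomial around expected abundances, with
  per-library lognormal size jitter; spike-ins are drawn the same way from
  fixed input amounts.
* Target repression in the transcriptome is exponential in cumulative
  loaded-miRNA pressure; CLASH chimeras are sampled proportionally to
  loaded abundance times target affinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Assay,
    CountMatrix,
    Genotype,
    HairpinAnnotation,
    Interval,
    SampleMeta,
)
from .strands import LoadingParams, score_catalog

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_GENOTYPE_STREAM = {Genotype.WT: 1, Genotype.HetKO: 2, Genotype.HM: 3, Genotype.IIIaMut: 4}


def revcomp_rna(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _default_spikes() -> dict[str, float]:
    # 8 spike-ins spanning a 128x ladder, on the same abundance scale as lambda
    return {f"spike{i + 1:02d}": float(2**i) for i in range(8)}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the simulator.  All rates are per processed precursor."""

    n_hairpins: int = 200
    mu_lambda: float = 0.0  # lognormal log-mean of transcription rate
    sigma_lambda: float = 0.7  # lognormal log-sd of transcription rate
    epsilon: float = 0.02  # residual 5p-arm cleavage in the HM genotype
    s_int_alpha: float = 0.3  # Beta shape for intermediate detectability
    s_int_beta: float = 0.3
    sigma_eta: float = 1.0  # sd of per-hairpin duplex-competition offset (score units)
    loading: LoadingParams = field(default_factory=LoadingParams)
    rho: float = 5.0  # AGO protection multiplier for loaded strands (>= 1)
    delta: float = 0.5  # unloaded-strand survival, (0, 1]
    phi: float = 0.1  # NB dispersion: var = m + phi * m^2
    depth: float = 1e6  # expected total-RNA reads per library
    ip_depth: float = 5e5  # expected AGO-IP reads per library
    lib_sigma: float = 0.15  # lognormal sd of per-library size jitter
    spike_in_amounts: Mapping[str, float] = field(default_factory=_default_spikes)
    repression_strength: float = 1.5  # r in exp(-r * pressure)
    n_genes: int = 500
    gene_baseline_mu: float = np.log(300.0)
    gene_baseline_sigma: float = 1.0
    hetko_dosage: float = 1.0  # HetKO transcription multiplier (compensated: 1.0)
    clash_background: float = 0.2  # fraction of non-chimeric reads
    noise: bool = True  # False: counts are rounded expectations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hairpins < 1:
            raise ValueError("n_hairpins must be >= 1")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        if not 0 < self.delta <= 1:
            raise ValueError("delta must be in (0, 1]")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if not 0 <= self.clash_background <= 1:
            raise ValueError("clash_background must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Expected abundances and loading probabilities for one genotype.

    ``strands`` is indexed by species id with columns: hairpin_id, arm,
    lam, s_int, p_load, abundance (expected steady-state, spike-in scale),
    loaded (expected AGO-resident abundance) and expected_counts (at the
    genotype's base library size factor, before jitter).
    """

    genotype: Genotype
    strands: pd.DataFrame
    scores: pd.DataFrame
    base_size_factor: float
    params: SimulationParams


# ---------------------------------------------------------------------------
# Catalog generation
# ---------------------------------------------------------------------------

def generate_catalog(
    n: int,
    seed: int,
    mismatch_rate: float = 0.10,
    paired_min: int = 18,
    paired_max: int = 21,
    loop_min: int = 12,
    loop_max: int = 18,
) -> list[HairpinAnnotation]:
    """Random hairpin catalog whose duplexes have 2-nt 3' overhangs on both strands.

    Arms are near-reverse-complements (>= 80% paired); the 5'-terminal
    nucleotide of each arm is sampled uniformly over {A,C,G,U} (with its
    partner forced complementary) so asymmetry scores span their full range
    and both guide-5p and guide-3p duplexes occur.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([seed, 101])
    bases = np.array(list("ACGU"))
    catalog: list[HairpinAnnotation] = []
    for k in range(n):
        P = int(rng.integers(paired_min, paired_max + 1))
        loop_len = int(rng.integers(loop_min, loop_max + 1))
        a = list(rng.choice(bases, size=P + 2))  # 5p arm: P paired + 2-nt 3' overhang
        b = [_COMPLEMENT[a[P - 1 - i]] for i in range(P)]  # paired region of 3p arm
        b += list(rng.choice(bases, size=2))  # 2-nt 3' overhang at hairpin terminus
        # force uniform 5'-terminal nucleotides with complementary partners
        a[0] = str(rng.choice(bases))
        b[P - 1] = _COMPLEMENT[a[0]]
        b[0] = str(rng.choice(bases))
        a[P - 1] = _COMPLEMENT[b[0]]
        # sprinkle internal mismatches, keeping >= 80% of the register paired
        # and never touching the first three pairs at either 5' end
        protected = {0, 1, 2, P - 1, P - 2, P - 3}
        candidates = [i for i in range(P) if i not in protected]
        max_mm = max(0, int(0.2 * P) - 0)
        n_mm = min(rng.binomial(len(candidates), mismatch_rate), max_mm)
        for i in rng.choice(candidates, size=n_mm, replace=False) if n_mm else []:
            alt = [c for c in "ACGU" if c != _COMPLEMENT[a[int(i)]]]
            b[P - 1 - int(i)] = str(rng.choice(alt))
        loop_seq = "".join(rng.choice(bases, size=loop_len))
        seq = "".join(a) + loop_seq + "".join(b)
        arm_len = P + 2
        catalog.append(
            HairpinAnnotation(
                hairpin_id=f"hp{k + 1:04d}",
                sequence=seq,
                arm5p=Interval(0, arm_len),
                loop=Interval(arm_len, arm_len + loop_len),
                arm3p=Interval(arm_len + loop_len, arm_len + loop_len + arm_len),
                overhang3p_len=2,
                duplex_pairs=tuple((i, P - 1 - i) for i in range(P)),
            )
        )
    return catalog


# ---------------------------------------------------------------------------
# Per-hairpin latent parameters (shared across genotypes)
# ---------------------------------------------------------------------------

def hairpin_latents(catalog: Sequence[HairpinAnnotation], params: SimulationParams) -> pd.DataFrame:
    """Transcription rates and intermediate detectabilities, drawn once per
    catalog+seed so every genotype sees the same hairpin-level biology."""
    rng = np.random.default_rng([params.seed, 201])
    n = len(catalog)
    lam = rng.lognormal(params.mu_lambda, params.sigma_lambda, size=n)
    s_int = rng.beta(params.s_int_alpha, params.s_int_beta, size=n)
    # duplex-competition offset: structural strand-selection determinants beyond
    # the 5'-end score (shifts which strand wins the duplex, not nicked loading)
    eta = rng.normal(0.0, params.sigma_eta, size=n)
    return pd.DataFrame(
        {"lam": lam, "s_int": s_int, "eta": eta},
        index=pd.Index([h.hairpin_id for h in catalog], name="hairpin_id"),
    )


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def _sigma(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def expected_abundances(
    catalog: Sequence[HairpinAnnotation],
    genotype: Genotype,
    params: SimulationParams,
    latents: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expected steady-state strand abundances and loading for one genotype.

    Returns (strands, scores).  Per hairpin the summed strand abundance never
    exceeds lam * (rho + 1): at most one loaded strand (x rho) plus one
    unloaded strand surviving at most fully.
    """
    if not isinstance(genotype, Genotype):
        raise ValueError(f"unknown genotype {genotype!r}")
    if not catalog:
        raise ValueError("catalog is empty")
    lat = latents if latents is not None else hairpin_latents(catalog, params)
    scores = score_catalog(catalog)
    lam = lat["lam"].to_numpy() * (params.hetko_dosage if genotype == Genotype.HetKO else 1.0)
    s_int = lat["s_int"].to_numpy()
    lp = params.loading
    s5 = scores["s5p"].to_numpy()
    s3 = scores["s3p"].to_numpy()
    eta = lat["eta"].to_numpy() if "eta" in lat else np.zeros_like(s5)
    delta_s = s5 - s3 + eta  # eta: hairpin-level bias in the duplex competition
    rho, dlt = params.rho, params.delta

    p5_dup = lp.efficiency * _sigma(delta_s / lp.tau)
    p3_dup = lp.efficiency * _sigma(-delta_s / lp.tau)
    p3_nick = _sigma((s3 - lp.s0) / lp.tau)  # NICK_5P: free 3p, own score only
    p5_nick = (1.0 - lp.kappa) * _sigma((s5 - lp.s0) / lp.tau)  # NICK_3P: occluded free 5p

    zero = np.zeros_like(lam)
    if genotype in (Genotype.WT, Genotype.HetKO):
        p5, p3 = p5_dup, p3_dup
        ab5 = lam * (p5 * rho + (1 - p5) * dlt)
        ab3 = lam * (p3 * rho + (1 - p3) * dlt)
        ab5loop = zero
        ab3loop = zero
        ld5, ld3 = lam * p5 * rho, lam * p3 * rho
    elif genotype == Genotype.HM:
        eps = params.epsilon
        p5 = eps * p5_dup
        p3 = eps * p3_dup + (1 - eps) * p3_nick
        ab5 = eps * lam * (p5_dup * rho + (1 - p5_dup) * dlt)
        ab3 = lam * (
            eps * (p3_dup * rho + (1 - p3_dup) * dlt)
            + (1 - eps) * (p3_nick * rho + (1 - p3_nick) * dlt)
        )
        ab5loop = (1 - eps) * lam * s_int
        ab3loop = zero
        ld5 = eps * lam * p5_dup * rho
        ld3 = lam * (eps * p3_dup + (1 - eps) * p3_nick) * rho
    else:  # IIIaMut
        p5, p3 = p5_nick, zero
        ab5 = lam * (p5_nick * rho + (1 - p5_nick) * dlt)
        ab3 = zero
        ab5loop = zero
        ab3loop = lam * s_int
        ld5, ld3 = lam * p5_nick * rho, zero

    hids = [h.hairpin_id for h in catalog]
    frames = []
    for arm, ab, ld, pl in (
        ("5p", ab5, ld5, p5),
        ("3p", ab3, ld3, p3),
        ("5pLoop", ab5loop, zero, zero),
        ("3pLoop", ab3loop, zero, zero),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "hairpin_id": hids,
                    "arm": arm,
                    "lam": lam,
                    "s_int": s_int,
                    "p_load": pl,
                    "abundance": ab,
                    "loaded": ld,
                },
                index=pd.Index([f"{h}-{arm}" for h in hids], name="species_id"),
            )
        )
    strands = pd.concat(frames)
    return strands, scores


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with var = m + phi*m^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        size = 1.0 / phi
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_expression(
    catalog: Sequence[HairpinAnnotation],
    genotype: Genotype,
    params: SimulationParams,
    n_replicates: int = 6,
    latents: pd.DataFrame | None = None,
) -> tuple[GroundTruth, CountMatrix, CountMatrix]:
    """Simulate total-RNA and AGO-IP miR-seq libraries for one genotype.

    Returns (ground_truth, total_counts, ago_ip_counts).  Total libraries
    carry spike-in counts in their sample metadata; AGO-IP libraries sample
    loaded-RISC abundance only and have an independent library size.
    """
    strands, scores = expected_abundances(catalog, genotype, params, latents)
    spike_amounts = dict(params.spike_in_amounts)
    total_mass = float(strands["abundance"].sum()) + float(sum(spike_amounts.values()))
    base_sf = params.depth / total_mass
    strands = strands.assign(expected_counts=strands["abundance"] * base_sf)

    loaded_mass = float(strands["loaded"].sum())
    ip_sf = params.ip_depth / loaded_mass if loaded_mass > 0 else 0.0

    rng = np.random.default_rng([params.seed, _GENOTYPE_STREAM[genotype], 301])
    total_cols, ip_cols = {}, {}
    total_meta, ip_meta = {}, {}
    spike_ids = sorted(spike_amounts)
    for r in range(1, n_replicates + 1):
        jit_t = rng.lognormal(0.0, params.lib_sigma) if params.noise else 1.0
        jit_i = rng.lognormal(0.0, params.lib_sigma) if params.noise else 1.0
        mean_t = strands["abundance"].to_numpy() * base_sf * jit_t
        mean_i = strands["loaded"].to_numpy() * ip_sf * jit_i
        mean_s = np.array([spike_amounts[s] for s in spike_ids]) * base_sf * jit_t
        if params.noise:
            counts_t = _nb_draw(rng, mean_t, params.phi)
            counts_i = _nb_draw(rng, mean_i, params.phi)
            # spike-ins are defined synthetic oligos: Poisson sampling noise only
            counts_s = rng.poisson(mean_s)
        else:
            counts_t = np.rint(mean_t).astype(np.int64)
            counts_i = np.rint(mean_i).astype(np.int64)
            counts_s = np.rint(mean_s).astype(np.int64)
        sid_t = f"{genotype.value}_total_r{r}"
        sid_i = f"{genotype.value}_ip_r{r}"
        total_cols[sid_t] = counts_t
        ip_cols[sid_i] = counts_i
        total_meta[sid_t] = SampleMeta(
            sid_t, genotype, Assay.total, r,
            {s: int(c) for s, c in zip(spike_ids, counts_s)},
        )
        ip_meta[sid_i] = SampleMeta(sid_i, genotype, Assay.ago_ip, r, {})
    idx = strands.index
    total = CountMatrix(pd.DataFrame(total_cols, index=idx), total_meta)
    ip = CountMatrix(pd.DataFrame(ip_cols, index=idx), ip_meta)
    gt = GroundTruth(genotype, strands, scores, base_sf, params)
    return gt, total, ip


def expected_log2fc(
    gt_a: GroundTruth, gt_b: GroundTruth, pseudocount: float = 1.0
) -> pd.Series:
    """Noise-free log2 fold change (B over A) on a shared spike-anchored count scale."""
    sf = 0.5 * (gt_a.base_size_factor + gt_b.base_size_factor)
    a = gt_a.strands["abundance"] * sf + pseudocount
    b = gt_b.strands["abundance"] * sf + pseudocount
    return np.log2(b / a)


def guide_truth(gt_wt: GroundTruth) -> pd.Series:
    """Generator-level guide arm per hairpin from WT expected counts, using the
    same >70% / >100-read rule the analysis applies."""
    from .strands import classify_strands

    ec = gt_wt.strands["expected_counts"]
    out = {}
    for hid in gt_wt.strands["hairpin_id"].unique():
        call = classify_strands(float(ec.get(f"{hid}-5p", 0.0)), float(ec.get(f"{hid}-3p", 0.0)), hid)
        out[hid] = call.guide_arm
    return pd.Series(out, name="guide_arm")


def planted_switch_set(
    gt_wt: GroundTruth, gt_hm: GroundTruth, lfc_threshold: float = 1.0
) -> set[str]:
    """Passenger 3p species whose expected HM/WT ratio exceeds the switch
    threshold - the generator's planted strand-switch set."""
    guides = guide_truth(gt_wt)
    lfc = expected_log2fc(gt_wt, gt_hm)
    out = set()
    for hid, guide in guides.items():
        if guide != "5p":
            continue
        sp = f"{hid}-3p"
        if float(lfc.get(sp, 0.0)) > lfc_threshold:
            out.add(sp)
    return out


# ---------------------------------------------------------------------------
# Target map, transcriptome and UTRs
# ---------------------------------------------------------------------------

def generate_target_map(
    catalog: Sequence[HairpinAnnotation],
    params: SimulationParams,
    mean_targets_per_gene: float = 0.7,
) -> pd.DataFrame:
    """TargetScan-style prediction table over synthetic genes.

    Each gene is assigned 1 + Poisson(mean) predicted miRNA regulators drawn
    uniformly from all mature species, with a context score (more negative =
    stronger) whose magnitude doubles as the repression affinity a_mg.
    """
    rng = np.random.default_rng([params.seed, 401])
    species = [f"{h.hairpin_id}-{arm}" for h in catalog for arm in ("5p", "3p")]
    rows = []
    for g in range(1, params.n_genes + 1):
        gene = f"g{g:05d}"
        k = 1 + int(rng.poisson(mean_targets_per_gene))
        k = min(k, len(species))
        partners = rng.choice(len(species), size=k, replace=False)
        for m in partners:
            ctx = -float(np.clip(np.abs(rng.normal(0.4, 0.2)), 0.05, 1.2))
            rows.append({"mirna_id": species[int(m)], "gene_id": gene, "context_score": ctx})
    table = pd.DataFrame(rows)
    table["affinity"] = -table["context_score"]
    return table


def simulate_transcriptome(
    truths: Mapping[Genotype, GroundTruth],
    target_map: pd.DataFrame,
    params: SimulationParams,
    n_replicates: int = 6,
) -> tuple[pd.DataFrame, CountMatrix]:
    """Gene-level RNA-seq counts under miRNA pressure for each genotype.

    Gene mean = baseline * exp(-r * sum_m a_mg * loaded_m / mean WT loaded).
    Returns (gene_truth, counts): gene_truth holds the baseline and the
    expected repression factor per genotype.
    """
    if (target_map["affinity"] < 0).any():
        raise ValueError("negative affinity in target map")
    rng = np.random.default_rng([params.seed, 501])
    genes = [f"g{g:05d}" for g in range(1, params.n_genes + 1)]
    baseline = rng.lognormal(params.gene_baseline_mu, params.gene_baseline_sigma, size=len(genes))
    gene_truth = pd.DataFrame({"baseline": baseline}, index=pd.Index(genes, name="gene_id"))

    wt = truths.get(Genotype.WT)
    if wt is None:
        raise ValueError("transcriptome simulation needs a WT ground truth as reference")
    ref_scale = float(wt.strands.loc[wt.strands["arm"].isin(["5p", "3p"]), "loaded"].mean())

    cols, meta = {}, {}
    for genotype, gt in truths.items():
        loaded = gt.strands["loaded"]
        pressure = pd.Series(0.0, index=gene_truth.index)
        contrib = target_map.assign(
            w=target_map["affinity"] * loaded.reindex(target_map["mirna_id"]).fillna(0.0).to_numpy()
        )
        summed = contrib.groupby("gene_id")["w"].sum() / ref_scale
        pressure.loc[summed.index] = summed
        factor = np.exp(-params.repression_strength * pressure)
        gene_truth[f"repression_{genotype.value}"] = factor
        mean_expr = baseline * factor.to_numpy()
        rng_g = np.random.default_rng([params.seed, _GENOTYPE_STREAM[genotype], 502])
        for r in range(1, n_replicates + 1):
            jit = rng_g.lognormal(0.0, params.lib_sigma) if params.noise else 1.0
            mean_r = mean_expr * jit
            counts = _nb_draw(rng_g, mean_r, params.phi) if params.noise else np.rint(mean_r).astype(np.int64)
            sid = f"{genotype.value}_rna_r{r}"
            cols[sid] = counts
            meta[sid] = SampleMeta(sid, genotype, Assay.rna_seq, r, {})
    counts = CountMatrix(pd.DataFrame(cols, index=gene_truth.index), meta)
    return gene_truth, counts


def generate_utrs(
    target_map: pd.DataFrame,
    catalog: Sequence[HairpinAnnotation],
    params: SimulationParams,
    min_len: int = 150,
    site_spacing: int = 30,
) -> tuple[dict[str, str], dict[tuple[str, str], int]]:
    """Synthetic 3' UTRs with one planted 8mer seed-match site per predicted
    miRNA-gene interaction.  Returns (utr_by_gene, site_position_by_pair)."""
    rng = np.random.default_rng([params.seed, 601])
    mature = {
        f"{h.hairpin_id}-{arm}": h.mature_seq(arm) for h in catalog for arm in ("5p", "3p")
    }
    bases = np.array(list("ACGU"))
    utrs: dict[str, str] = {}
    sites: dict[tuple[str, str], int] = {}
    for gene, group in target_map.groupby("gene_id"):
        k = len(group)
        length = max(min_len, 20 + site_spacing * k + 40)
        seq = list(rng.choice(bases, size=length))
        for i, mirna in enumerate(group["mirna_id"]):
            # 8mer site: perfect match to miRNA positions 2-8 plus an A across
            # from position 1 (mRNA 5'->3': revcomp(m[1:8]) then A)
            site = revcomp_rna(mature[mirna][1:8]) + "A"
            pos = 20 + site_spacing * i
            seq[pos : pos + len(site)] = list(site)
            sites[(mirna, gene)] = pos
        utrs[gene] = "".join(seq)
    return utrs, sites


# ---------------------------------------------------------------------------
# CLASH read simulation
# ---------------------------------------------------------------------------

def simulate_clash_reads(
    gt: GroundTruth,
    catalog: Sequence[HairpinAnnotation],
    target_map: pd.DataFrame,
    utrs: Mapping[str, str],
    sites: Mapping[tuple[str, str], int],
    n_reads: int,
    seed: int,
    background_fraction: float | None = None,
    fragment_len: tuple[int, int] = (20, 40),
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Chimeric AGO-CLASH reads for one genotype plus per-read ground truth.

    Each true chimera is a full mature miRNA ligated 5' of a 20-40 nt UTR
    fragment containing its planted seed-match site; hybrid frequency is
    proportional to loaded abundance x affinity.  Background reads (random
    inserts and unligated mature miRNAs) make up ``background_fraction``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    bg_frac = gt.params.clash_background if background_fraction is None else background_fraction
    rng = np.random.default_rng([seed, _GENOTYPE_STREAM[gt.genotype], 701])
    mature = {
        f"{h.hairpin_id}-{arm}": h.mature_seq(arm) for h in catalog for arm in ("5p", "3p")
    }
    loaded = gt.strands["loaded"]
    weights = target_map["affinity"].to_numpy() * loaded.reindex(
        target_map["mirna_id"]
    ).fillna(0.0).to_numpy()
    total_w = weights.sum()
    n_bg = int(round(n_reads * bg_frac))
    n_hyb = n_reads - n_bg if total_w > 0 else 0
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    bases = np.array(list("ACGU"))

    if n_hyb > 0:
        probs = weights / total_w
        picks = rng.choice(len(target_map), size=n_hyb, p=probs)
        for i, row_i in enumerate(picks):
            row = target_map.iloc[int(row_i)]
            mirna, gene = row["mirna_id"], row["gene_id"]
            utr = utrs[gene]
            pos = sites[(mirna, gene)]
            flen = int(rng.integers(fragment_len[0], fragment_len[1] + 1))
            max_off = min(flen - 8, pos)
            off = int(rng.integers(0, max_off + 1))
            start = pos - off
            frag = utr[start : start + flen]
            rid = f"hyb{i + 1:06d}"
            reads.append((rid, mature[mirna] + frag))
            truth_rows.append(
                {
                    "read_id": rid,
                    "mirna_id": mirna,
                    "gene_id": gene,
                    "target_start": start,
                    "is_background": False,
                }
            )
    for j in range(n_bg):
        rid = f"bg{j + 1:06d}"
        if rng.random() < 0.5:
            seq = "".join(rng.choice(bases, size=int(rng.integers(40, 71))))
        else:
            seq = mature[str(rng.choice(list(mature)))]
        reads.append((rid, seq))
        truth_rows.append(
            {"read_id": rid, "mirna_id": "", "gene_id": "", "target_start": -1, "is_background": True}
        )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "mirna_id", "gene_id", "target_start", "is_background"]
    ).set_index("read_id")
    return reads, truth


# ---------------------------------------------------------------------------
# Read-level emission (for end-to-end quantification tests)
# ---------------------------------------------------------------------------

def reads_from_counts(
    catalog: Sequence[HairpinAnnotation], matrix: CountMatrix
) -> dict[str, list[str]]:
    """Expand a raw species count matrix into exact annotated read sequences.

    Every count becomes one read synthesized verbatim from the catalog
    (mature arms, 5p+loop and 3p+loop products), so classification can be
    checked against the generator's labels with zero read-level noise.
    """
    seq_of: dict[str, str] = {}
    for h in catalog:
        seq_of[f"{h.hairpin_id}-5p"] = h.arm5p_seq
        seq_of[f"{h.hairpin_id}-3p"] = h.arm3p_seq
        seq_of[f"{h.hairpin_id}-5pLoop"] = h.five_p_loop_seq
        seq_of[f"{h.hairpin_id}-3pLoop"] = h.three_p_loop_seq
    out: dict[str, list[str]] = {}
    for sid in matrix.data.columns:
        col = matrix.data[sid]
        reads: list[str] = []
        for species, count in col.items():
            if count > 0 and species in seq_of:
                reads.extend([seq_of[species]] * int(count))
        out[sid] = reads
    return out
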