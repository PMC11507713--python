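"""Synthetic diploid panels with planted regulatory variant effects.

Generates everything the downstream pipeline needs without external data:
a random reference genome, a panel of diploid individuals carrying
biallelic SNPs at sampled allele frequencies, divergently transcribed
initiation elements (two opposing-strand modes ~110 bp apart), planted
quantity-modulating and directionality-modulating variant effects, and
noisy strand-specific base-resolution coverage per individual.

Planted effects are *sequence-decodable*: a causal SNP toggles a fixed
8-mer motif (one motif controls element quantity, another controls strand
allocation), with the per-allele effect magnitude set by the configured
standard deviation and a random sign depending on whether the alternate
allele creates or breaks the motif. Marginally over many effects the
effect-size distribution is centered at zero with the configured spread,
while remaining learnable by a sequence model on held-out loci.

Per-element totals are negative-binomial around
``base_rate * 2^(dosage * quantity_log2fc)``; the plus-strand share is
``logistic(base_logit + dosage * directionality_logit)``; read positions
are discretized Gaussian bumps (sd 15 bp by default) around the two
strand modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import BASES, CoverageWindow, GenomicWindow

__all__ = [
    "SimConfig",
    "SimulatedPanel",
    "QUANTITY_MOTIF",
    "DIRECTIONALITY_MOTIF",
    "simulate_reference",
    "place_elements",
    "embed_element_motifs",
    "simulate_genotypes",
    "plant_effects",
    "simulate_coverage",
    "simulate_panel",
]

#: activator motif: embedded copies set an element's base rate, and causal
#: quantity SNPs create or break one copy — so the regulatory grammar a
#: model learns across loci transfers directly to variant effects
QUANTITY_MOTIF = "TGACTCAG"
#: strand-allocation motif, same scheme for the directional balance
DIRECTIONALITY_MOTIF = "CACGTGAC"
#: written just upstream of each strand's initiation mode (reverse
#: complement on the minus strand) so profile positions are decodable
INITIATOR_MOTIF = "TATAAGCC"


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 20000
    n_chromosomes: int = 10
    n_individuals: int = 20
    n_elements: int = 50
    #: bp between the opposing-strand initiation modes of an element
    element_spacing: int = 110
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.1, 0.5)
    causal_fraction: float = 0.25
    #: per-allele |log2 fold change| of planted quantity effects
    quantity_effect_sd: float = 1.0
    #: per-allele |logit shift| of planted strand-allocation effects
    directionality_effect_sd: float = 1.0
    #: negative-binomial overdispersion of per-element totals (0 = Poisson)
    dispersion: float = 0.1
    seed: int = 0
    # -- generator stipulations not fixed by the analysis ------------------
    #: median per-element read count
    base_rate: float = 200.0
    #: residual (sequence-independent) log2 spread of per-element rates
    base_rate_log2_sd: float = 0.3
    #: per-copy log2 rate contribution of embedded quantity-motif copies;
    #: coherent with SNP effects when ~ 2 x quantity_effect_sd (a diploid
    #: copy carries two alleles)
    strength_log2_per_copy: float = 1.6
    max_strength_copies: int = 2
    #: per-copy logit contribution of embedded directionality-motif copies
    direction_logit_per_copy: float = 2.0
    max_direction_copies: int = 2
    #: write initiator/strength motifs into the reference at each element
    embed_element_motifs: bool = True
    bump_sd: float = 15.0
    base_logit: float = 0.0
    #: fraction of causal SNPs that modulate directionality (rest: quantity)
    directionality_fraction: float = 0.5
    #: causal SNPs must lie within this window around their element center
    effect_window: int = 1000
    #: center-to-center distance between adjacent elements
    element_pitch: int = 1300
    #: extra libraries duplicating the first donors (isogenic replicates)
    n_isogenic_duplicates: int = 0

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_chromosomes", "n_individuals",
                     "n_elements", "element_spacing", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names}


@dataclass
class SimulatedPanel:
    config: SimConfig
    reference: dict[str, str]
    elements: pd.DataFrame
    snps: pd.DataFrame
    genotypes: np.ndarray  # (n_libraries, n_snps) alt-allele dosages
    libraries: list[str]
    donors: list[str]
    coverage: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    truth: pd.DataFrame
    peaks: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}

    def snps_in_window(self, window: GenomicWindow) -> pd.DataFrame:
        s = self.snps
        return s[(s.chrom == window.chrom) & (s.pos >= window.start) & (s.pos < window.end)]

    def coverage_window(self, library: str, window: GenomicWindow) -> CoverageWindow:
        plus, minus = self.coverage[library][window.chrom]
        return CoverageWindow(plus[window.start:window.end].astype(np.float64),
                              minus[window.start:window.end].astype(np.float64),
                              window)

    def library_totals(self, library: str) -> float:
        return sum(float(p.sum()) + float(m.sum())
                   for p, m in self.coverage[library].values())


def simulate_reference(config: SimConfig,
                       rng: np.random.Generator | None = None) -> dict[str, str]:
    """Uniform-random A/C/G/T chromosomes, reproducible under the seed."""
    rng = rng or np.random.default_rng(config.seed)
    bases = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return {chrom: bases[rng.integers(0, 4, size=config.genome_length)].tobytes().decode()
            for chrom in config.chrom_names}


def place_elements(config: SimConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Divergent initiation elements on a jittered grid, with log-normal
    per-element base rates and the two strand modes ``element_spacing`` bp
    apart (minus-strand mode upstream of the plus-strand mode)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    margin = config.effect_window // 2 + 300
    usable = config.genome_length - 2 * margin
    per_chrom = max(0, usable // config.element_pitch + 1)
    capacity = per_chrom * config.n_chromosomes
    if config.n_elements > capacity:
        raise ValueError(f"cannot place {config.n_elements} elements; capacity {capacity} "
                         "(increase genome_length or reduce element_pitch)")
    slots = [(chrom, margin + i * config.element_pitch)
             for chrom in config.chrom_names for i in range(per_chrom)]
    chosen = sorted(rng.choice(len(slots), size=config.n_elements, replace=False))
    rows = []
    half = config.element_spacing // 2
    for eid, si in enumerate(chosen):
        chrom, base_center = slots[si]
        center = base_center + int(rng.integers(-50, 51))
        q_copies = int(rng.integers(0, config.max_strength_copies + 1))
        d_copies = int(rng.integers(0, config.max_direction_copies + 1))
        log2_rate = (config.strength_log2_per_copy
                     * (q_copies - config.max_strength_copies / 2.0)
                     + rng.normal(0.0, config.base_rate_log2_sd))
        logit = (config.base_logit + config.direction_logit_per_copy
                 * (d_copies - config.max_direction_copies / 2.0))
        rows.append({"element_id": f"elem{eid}", "chrom": chrom, "center": center,
                     "plus_mode": center + half, "minus_mode": center - half,
                     "base_rate": config.base_rate * 2.0 ** log2_rate,
                     "base_logit": logit,
                     "strength_copies": q_copies, "direction_copies": d_copies})
    return pd.DataFrame(rows)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: offsets (relative to element center) of the slots that embedded motif
#: copies may occupy, outside the planted-effect region around the center
_MOTIF_SLOTS = (-142, -130, -118, 106, 118, 130)


def embed_element_motifs(config: SimConfig, elements: pd.DataFrame,
                         reference: dict[str, str],
                         rng: np.random.Generator | None = None) -> dict[str, str]:
    """Write the sequence determinants of each element into the reference:
    an initiator motif upstream of each strand mode plus the element's
    quantity- and directionality-motif copies at randomized slots."""
    rng = rng or np.random.default_rng(config.seed + 5)
    ref = {c: bytearray(s.encode()) for c, s in reference.items()}
    ini = INITIATOR_MOTIF.encode()
    ini_rc = _revcomp(INITIATOR_MOTIF).encode()
    for elem in elements.itertuples():
        seq = ref[elem.chrom]
        seq[elem.plus_mode - 10:elem.plus_mode - 10 + len(ini)] = ini
        mstart = elem.minus_mode + 2
        seq[mstart:mstart + len(ini_rc)] = ini_rc
        order = rng.permutation(len(_MOTIF_SLOTS))
        n_q = int(elem.strength_copies)
        for rank, slot in enumerate(order[:n_q + int(elem.direction_copies)]):
            motif = (QUANTITY_MOTIF if rank < n_q else DIRECTIONALITY_MOTIF).encode()
            start = elem.center + _MOTIF_SLOTS[slot]
            seq[start:start + len(motif)] = motif
    return {c: bytes(s).decode() for c, s in ref.items()}


def simulate_genotypes(config: SimConfig, reference: dict[str, str],
                       rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Biallelic SNPs at unique positions with binomial dosages.

    Returns (dosage matrix of shape (n_individuals, n_snps), SNP table).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    chroms = config.chrom_names
    glen = config.genome_length
    total = glen * len(chroms)
    if config.n_snps > total:
        raise ValueError(f"n_snps={config.n_snps} exceeds {total} available positions")
    flat = np.sort(rng.choice(total, size=config.n_snps, replace=False))
    rows = []
    for i, fp in enumerate(flat):
        chrom = chroms[fp // glen]
        pos = int(fp % glen)
        ref = reference[chrom][pos]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        maf = float(rng.uniform(*config.maf_range))
        rows.append({"snp_id": f"snp{i}", "chrom": chrom, "pos": pos,
                     "ref": ref, "alt": alt, "maf": maf})
    snps = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    dosages = rng.binomial(2, snps.maf.values[None, :],
                           size=(config.n_individuals, len(snps))).astype(np.int8)
    return dosages, snps


def _nearest_element(elements: pd.DataFrame, chrom: str, pos: int) -> tuple[str, int] | None:
    cand = elements[elements.chrom == chrom]
    if cand.empty:
        return None
    d = (cand.center - pos).abs()
    i = d.idxmin()
    return str(elements.element_id[i]), int(elements.center[i])


def plant_effects(config: SimConfig, snps: pd.DataFrame, elements: pd.DataFrame,
                  reference: dict[str, str],
                  rng: np.random.Generator | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Plant motif-toggling effects at a causal subset of eligible SNPs.

    A SNP is eligible when it falls within ``effect_window`` of an element
    center. Exactly ``round(causal_fraction * n_eligible)`` SNPs become
    causal; each gets either a quantity effect of magnitude
    ``quantity_effect_sd`` or a directionality effect of magnitude
    ``directionality_effect_sd`` (sign: + when the alternate allele creates
    the motif, - when it breaks it). The corresponding motif context is
    written into the reference around the SNP so the effect is decodable
    from sequence; the returned SNP table has ref/alt alleles refreshed
    against the modified reference.

    Returns (effect table, updated SNP table, updated reference).
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    half = config.effect_window // 2
    eligible = []
    for row in snps.itertuples():
        hit = _nearest_element(elements, row.chrom, row.pos)
        if hit is not None and abs(hit[1] - row.pos) <= half:
            eligible.append((row.Index, hit[0]))
    n_causal = round(config.causal_fraction * len(eligible))
    ref = {c: bytearray(s.encode()) for c, s in reference.items()}
    effects = []
    chosen = rng.choice(len(eligible), size=n_causal, replace=False) if n_causal else []
    motif_len = len(QUANTITY_MOTIF)
    for oi in chosen:
        snp_idx, element_id = eligible[oi]
        row = snps.iloc[snp_idx]
        is_dir = rng.random() < config.directionality_fraction
        motif = DIRECTIONALITY_MOTIF if is_dir else QUANTITY_MOTIF
        magnitude = config.directionality_effect_sd if is_dir else config.quantity_effect_sd
        # causal SNPs hit central motif positions, where any recognizer of
        # the motif is sensitive to them
        offset = int(rng.integers(2, 5))
        # keep the motif inside the chromosome (elements sit well inside,
        # so only pathological configs ever need the clamp)
        start = min(max(int(row.pos) - offset, 0), len(ref[row.chrom]) - motif_len)
        offset = int(row.pos) - start
        alt_creates = bool(rng.random() < 0.5)
        chrom_seq = ref[row.chrom]
        chrom_seq[start:start + motif_len] = motif.encode()
        motif_base = motif[offset]
        other = BASES[(BASES.index(motif_base) + int(rng.integers(1, 4))) % 4]
        if alt_creates:
            chrom_seq[row.pos] = ord(other)  # reference carries the broken motif
        sign = 1.0 if alt_creates else -1.0
        # a 'breaks' SNP leaves an intact motif copy on the reference; its
        # two reference alleles contribute a constant rate/logit offset so
        # the element's output stays coherent with motif counting
        offset = 0.0 if alt_creates else 2.0 * magnitude
        effects.append({
            "snp_id": row.snp_id, "element_id": element_id,
            "quantity_log2fc": 0.0 if is_dir else sign * magnitude,
            "directionality_logit": sign * magnitude if is_dir else 0.0,
            "quantity_offset_log2": 0.0 if is_dir else offset,
            "directionality_offset_logit": offset if is_dir else 0.0,
            "alt_allele": motif_base if alt_creates else other,
        })
    new_reference = {c: bytes(s).decode() for c, s in ref.items()}

    snps = snps.copy()
    effect_alt = {e["snp_id"]: e["alt_allele"] for e in effects}
    for i in snps.index:
        chrom, pos = snps.at[i, "chrom"], snps.at[i, "pos"]
        new_ref = new_reference[chrom][pos]
        snps.at[i, "ref"] = new_ref
        sid = snps.at[i, "snp_id"]
        if sid in effect_alt:
            snps.at[i, "alt"] = effect_alt[sid]
        if snps.at[i, "alt"] == new_ref:  # motif rewrite collided with alt
            snps.at[i, "alt"] = BASES[(BASES.index(new_ref) + 1) % 4]
    truth = pd.DataFrame(effects, columns=["snp_id", "element_id", "quantity_log2fc",
                                           "directionality_logit",
                                           "quantity_offset_log2",
                                           "directionality_offset_logit"])
    return truth, snps, new_reference


def simulate_coverage(config: SimConfig, elements: pd.DataFrame, snps: pd.DataFrame,
                      genotypes: np.ndarray, truth: pd.DataFrame, libraries: list[str],
                      rng: np.random.Generator | None = None
                      ) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-library strand-specific integer coverage across the genome."""
    rng = rng or np.random.default_rng(config.seed + 4)
    n_lib = len(libraries)
    if genotypes.shape[0] != n_lib:
        raise ValueError("genotype rows must match libraries")
    snp_col = {sid: j for j, sid in enumerate(snps.snp_id)}
    coverage = {lib: {c: (np.zeros(config.genome_length, np.int32),
                          np.zeros(config.genome_length, np.int32))
                      for c in config.chrom_names} for lib in libraries}
    by_elem = truth.groupby("element_id") if not truth.empty else None
    half_span = config.element_pitch // 2
    for elem in elements.itertuples():
        q_shift = np.zeros(n_lib)
        logit = np.full(n_lib, float(elem.base_logit))
        if by_elem is not None and elem.element_id in by_elem.groups:
            for eff in by_elem.get_group(elem.element_id).itertuples():
                dos = genotypes[:, snp_col[eff.snp_id]].astype(np.float64)
                q_shift += dos * eff.quantity_log2fc + \
                    getattr(eff, "quantity_offset_log2", 0.0)
                logit += dos * eff.directionality_logit + \
                    getattr(eff, "directionality_offset_logit", 0.0)
        mean = elem.base_rate * 2.0 ** q_shift
        if config.dispersion > 0:
            lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mean)
        else:
            lam = mean
        totals = rng.poisson(lam)
        p_plus = 1.0 / (1.0 + np.exp(-logit))
        n_plus = rng.binomial(totals, p_plus)
        lo = max(0, elem.center - half_span)
        hi = min(config.genome_length, elem.center + half_span)
        for li, lib in enumerate(libraries):
            plus_arr, minus_arr = coverage[lib][elem.chrom]
            for count, mode, arr in ((n_plus[li], elem.plus_mode, plus_arr),
                                     (totals[li] - n_plus[li], elem.minus_mode, minus_arr)):
                if count == 0:
                    continue
                pos = np.clip(np.rint(rng.normal(mode, config.bump_sd, size=count)),
                              lo, hi - 1).astype(np.int64)
                np.add.at(arr, pos, 1)
    return coverage


def _peak_calls(elements: pd.DataFrame, half_width: int = 25) -> pd.DataFrame:
    rows = []
    for elem in elements.itertuples():
        for strand, mode in (("+", elem.plus_mode), ("-", elem.minus_mode)):
            rows.append({"chrom": elem.chrom, "start": int(mode) - half_width,
                         "end": int(mode) + half_width,
                         "name": f"{elem.element_id}{strand}", "score": 0,
                         "strand": strand})
    return pd.DataFrame(rows)


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Run the full generator: reference, elements, genotypes, planted
    effects, and per-library coverage (plus optional isogenic replicates)."""
    reference = simulate_reference(config)
    elements = place_elements(config)
    if config.embed_element_motifs:
        reference = embed_element_motifs(config, elements, reference,
                                         np.random.default_rng(config.seed + 5))
    genotypes, snps = simulate_genotypes(config, reference)
    truth, snps, reference = plant_effects(config, snps, elements, reference)

    donors = [f"donor{i}" for i in range(config.n_individuals)]
    libraries = list(donors)
    lib_rows = list(range(config.n_individuals))
    for r in range(config.n_isogenic_duplicates):
        di = r % config.n_individuals
        libraries.append(f"{donors[di]}_rep{r // config.n_individuals + 2}")
        donors.append(donors[di])
        lib_rows.append(di)
    lib_genotypes = genotypes[lib_rows, :]

    coverage = simulate_coverage(config, elements, snps, lib_genotypes, truth, libraries)
    return SimulatedPanel(config=config, reference=reference, elements=elements,
                          snps=snps, genotypes=lib_genotypes, libraries=libraries,
                          donors=donors, coverage=coverage, truth=truth,
                          peaks=_peak_calls(elements))
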