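"""Synthetic two-cohort antidepressant-trial data and genotype/phenotype file I/O.

This module provides the in-memory containers used throughout the package
(:class:`GenotypeMatrix`, :class:`HRSDPanel`, subject tables), a generative
model for two-cohort SSRI-trial data with known genetic ground truth, and
readers/writers for PLINK 1.9 binary genotypes and TSV phenotype files.

The generator emulates a two-centre major-depressive-disorder trial: subjects
enter with a 21-item Hamilton Rating Scale for Depression (HRSD-21) total of
at least 14, are assessed at weeks 0/2/4/8, and improve at subject-specific
rates that may depend additively on the dosage of designated causal variants.
Genotypes are drawn from a block-correlated haplotype pool so that
linkage-disequilibrium structure (pairwise r^2) is tunable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Sentinel for a missing genotype call (in-memory; PLINK's 2-bit code on disk).
MISSING: int = -1

#: Assessment weeks of the trial design.
WEEKS: tuple[int, ...] = (0, 2, 4, 8)

#: Declared per-item maxima of the HRSD-21 (item 1 "depressed mood" is 0-4).
ITEM_MAX: tuple[int, ...] = (4, 4, 4, 2, 2, 2, 4, 4, 2, 4, 4, 2, 2, 2, 2, 2, 4, 2, 2, 2, 2)

#: Largest possible HRSD-21 total under the declared item maxima.
MAX_TOTAL: int = sum(ITEM_MAX)

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])

# bed 2-bit code -> alt-allele count (A1 = alt in our bim files)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


@dataclass(frozen=True)
class VariantInfo:
    """Metadata for a single biallelic variant."""

    id: str
    chromosome: str
    position: int  # 1-based base pairs
    allele_ref: str
    allele_alt: str
    is_chip: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"ref and alt alleles identical for {self.id}")


class GenotypeMatrix:
    """Subjects x variants matrix of alt-allele counts in {0, 1, 2, MISSING}.

    Parameters
    ----------
    subjects
        Ordered subject identifiers (rows).
    variants
        Ordered :class:`VariantInfo` (columns).
    calls
        int8 array of shape ``(n_subjects, n_variants)`` with values in
        {0, 1, 2, MISSING}.
    """

    def __init__(self, subjects: Sequence[str], variants: Sequence[VariantInfo],
                 calls: np.ndarray) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(subjects), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(subjects)} subjects x {len(variants)} variants")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")
        if len(set(subjects)) != len(subjects):
            raise ValueError("subject ids must be unique")
        self.subjects = list(subjects)
        self.variants = list(variants)
        self.calls = calls

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def variant_frame(self) -> pd.DataFrame:
        """Variant metadata as a DataFrame (id, chromosome, position, alleles)."""
        return pd.DataFrame([dataclasses.asdict(v) for v in self.variants])

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls (nan if none)."""
        calls = self.calls.astype(float)
        calls[self.calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=0) / 2.0

    def subset_subjects(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.subjects.index(s) for s in keep]
        return GenotypeMatrix(list(keep), self.variants, self.calls[idx, :])

    def subset_variants(self, keep_idx: Sequence[int]) -> "GenotypeMatrix":
        keep_idx = list(keep_idx)
        return GenotypeMatrix(self.subjects, [self.variants[i] for i in keep_idx],
                              self.calls[:, keep_idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.subjects == other.subjects
                and self.variants == other.variants
                and np.array_equal(self.calls, other.calls))


class HRSDPanel:
    """Per-subject HRSD-21 item scores at weeks 0/2/4/8.

    Stored as an int16 array of shape ``(n_subjects, 4, 21)``; a wholly missing
    visit is encoded as a row of -1 and tracked in :attr:`observed`.
    """

    def __init__(self, subjects: Sequence[str], items: np.ndarray,
                 observed: np.ndarray) -> None:
        items = np.asarray(items, dtype=np.int16)
        observed = np.asarray(observed, dtype=bool)
        if items.shape != (len(subjects), len(WEEKS), 21):
            raise ValueError(f"items shape {items.shape} invalid")
        if observed.shape != (len(subjects), len(WEEKS)):
            raise ValueError(f"observed shape {observed.shape} invalid")
        maxima = np.array(ITEM_MAX, dtype=np.int16)
        obs_items = items[observed]
        if obs_items.size and ((obs_items < 0) | (obs_items > maxima)).any():
            raise ValueError("item scores outside declared ranges")
        self.subjects = list(subjects)
        self.items = items
        self.observed = observed

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def week_index(self, week: int) -> int:
        if week not in WEEKS:
            raise KeyError(f"week must be one of {WEEKS}, got {week}")
        return WEEKS.index(week)

    def subject_index(self, subject: str) -> int:
        try:
            return self.subjects.index(subject)
        except ValueError:
            raise KeyError(f"subject {subject!r} not in panel") from None

    def totals(self) -> np.ndarray:
        """HRSD totals, shape (n_subjects, 4); nan where the visit is missing."""
        tot = self.items.sum(axis=2).astype(float)
        tot[~self.observed] = np.nan
        return tot

    def item_scores(self, item: int) -> np.ndarray:
        """Scores of one 1-based item, shape (n_subjects, 4); nan where missing."""
        if not 1 <= item <= 21:
            raise KeyError(f"item must be 1..21, got {item}")
        sc = self.items[:, :, item - 1].astype(float)
        sc[~self.observed] = np.nan
        return sc

    def copy(self) -> "HRSDPanel":
        return HRSDPanel(list(self.subjects), self.items.copy(), self.observed.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HRSDPanel):
            return NotImplemented
        if self.subjects != other.subjects or not np.array_equal(self.observed, other.observed):
            return False
        return np.array_equal(self.items[self.observed], other.items[other.observed])


@dataclass
class SimulationConfig:
    """Configuration of the synthetic two-cohort trial.

    Defaults reproduce the study conditions the package targets: two cohorts of
    253 and 175 subjects with different sex/age mixes, LD-block genotypes with
    minor-allele frequencies in [0.05, 0.5], HRSD trajectories calibrated so
    that roughly 33% of subjects remit by week 8 and roughly 39% respond
    (>= 50% symptom reduction) by week 4, about 11% with moderately-severe or
    severe depressed mood (item 1 >= 3) at week 4, and visit-level missingness
    of about 92% complete / 7% one visit missing / 1% two-plus visits missing.
    """

    n_subjects: dict[str, int] = field(default_factory=lambda: {"A": 253, "B": 175})
    n_variants: int = 60
    block_size: int = 10
    block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    chromosome: str = "13"
    position_start: int = 47_400_000
    position_step: int = 500
    causal_effects: dict[str, float] = field(default_factory=dict)
    sex_male_frac: dict[str, float] = field(default_factory=lambda: {"A": 0.174, "B": 0.451})
    age_mean: dict[str, float] = field(default_factory=lambda: {"A": 41.0, "B": 47.4})
    age_sd: dict[str, float] = field(default_factory=lambda: {"A": 13.7, "B": 15.1})
    sex_improve_effect: float = 0.0
    age_improve_effect: float = 0.0
    baseline_extra_lam: float = 7.0
    improve_mean: float = 0.545
    improve_sd: float = 0.19
    time_exponent: float = 0.30
    visit_noise_sd: float = 2.0
    item1_weight: float = 9.7
    drug: str = "SSRI"
    missing_probs: tuple[float, float, float] = (0.92, 0.07, 0.01)
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_subjects.values()):
            raise ValueError("cohort sizes must be positive")
        if self.n_variants <= 0 or self.block_size <= 0:
            raise ValueError("n_variants and block_size must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.block_rho <= 1:
            raise ValueError("block_rho must be in [0, 1]")
        if abs(sum(self.missing_probs) - 1.0) > 1e-9:
            raise ValueError("missing_probs must sum to 1")
        if any(p < 0 for p in self.missing_probs):
            raise ValueError("missing_probs must be non-negative")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subject_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids, cohorts = [], []
    for cohort in sorted(config.n_subjects):
        for i in range(config.n_subjects[cohort]):
            ids.append(f"{cohort}{i + 1:04d}")
            cohorts.append(cohort)
    return ids, cohorts


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw genotypes from a block-correlated haplotype pool.

    Within each LD block every haplotype shares one latent standard-normal
    factor with weight ``sqrt(block_rho)``; an allele is present when the
    latent value falls below the normal quantile of the variant's target
    allele frequency, which yields tunable positive pairwise r^2 within a
    block and independence across blocks.  Two haplotypes per subject are
    summed, and each variant is then oriented so that the alt allele is the
    minor allele (realized frequency <= 0.5).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    ids, _ = _subject_ids(config)
    n = len(ids)
    m = config.n_variants
    target_af = rng.uniform(*config.maf_range, size=m)
    thresholds = stats.norm.ppf(target_af)

    calls = np.empty((n, m), dtype=np.int8)
    rho = config.block_rho
    for start in range(0, m, config.block_size):
        stop = min(start + config.block_size, m)
        width = stop - start
        dosage = np.zeros((n, width), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal(n)[:, None]
            indep = rng.standard_normal((n, width))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
            dosage += (z < thresholds[start:stop]).astype(np.int8)
        calls[:, start:stop] = dosage

    variants = []
    for j in range(m):
        ref, alt = "A", "G"
        freq = calls[:, j].mean() / 2.0
        if freq > 0.5:  # orient alt to the minor allele
            calls[:, j] = 2 - calls[:, j]
            ref, alt = alt, ref
        variants.append(VariantInfo(
            id=f"snp{j + 1:04d}",
            chromosome=config.chromosome,
            position=config.position_start + j * config.position_step,
            allele_ref=ref, allele_alt=alt))
    return GenotypeMatrix(ids, variants, calls)


def simulate_subjects(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the subject table (id, cohort, sex, age, drug).

    Sex is coded 1 = male, 2 = female (the PLINK fam convention used across
    the package); age is truncated below at 18 years.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    ids, cohorts = _subject_ids(config)
    sex = np.empty(len(ids), dtype=int)
    age = np.empty(len(ids), dtype=float)
    for i, cohort in enumerate(cohorts):
        sex[i] = 1 if rng.random() < config.sex_male_frac[cohort] else 2
        age[i] = max(18.0, rng.normal(config.age_mean[cohort], config.age_sd[cohort]))
    return pd.DataFrame({
        "subject_id": ids, "cohort": cohorts, "sex": sex,
        "age": np.round(age, 1), "drug": config.drug,
    })


def allocate_items(total: int, weights: Sequence[float] | None = None,
                   maxima: Sequence[int] = ITEM_MAX) -> np.ndarray:
    """Distribute an HRSD total over 21 items by largest-remainder allocation.

    Quotas proportional to ``weights`` are floored, capped at the item maxima,
    and leftover points are assigned one at a time by descending fractional
    remainder (ties broken by item order), skipping capped items.
    """
    maxima = np.asarray(maxima, dtype=int)
    if weights is None:
        weights = maxima.astype(float)
    w = np.asarray(weights, dtype=float)
    if w.shape != maxima.shape or (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative, same length as maxima, not all zero")
    total = int(total)
    if total < 0 or total > maxima.sum():
        raise ValueError(f"total {total} outside [0, {maxima.sum()}]")
    quota = total * w / w.sum()
    alloc = np.minimum(np.floor(quota).astype(int), maxima)
    remainder = quota - np.floor(quota)
    order = np.lexsort((np.arange(len(w)), -remainder))
    left = total - alloc.sum()
    while left > 0:
        progressed = False
        for j in order:
            if left == 0:
                break
            if alloc[j] < maxima[j]:
                alloc[j] += 1
                left -= 1
                progressed = True
        if not progressed:  # pragma: no cover - guarded by total <= sum(maxima)
            raise RuntimeError("allocation stuck below item maxima")
    return alloc


def simulate_trial(genotypes: GenotypeMatrix, config: SimulationConfig,
                   subjects: pd.DataFrame | None = None) -> tuple[pd.DataFrame, HRSDPanel]:
    """Simulate HRSD-21 trajectories for the genotyped subjects.

    Each subject starts at a baseline total of ``14 + Poisson(baseline_extra_lam)``
    (capped at the scale maximum) and improves by a fraction
    ``F * (week/8)**time_exponent`` of baseline, where the subject's week-8
    improvement fraction ``F`` is normal with configurable mean/sd, shifted
    additively by ``causal_effects[v] * dosage(v)`` plus optional sex/age
    terms, and clipped to [0, 1].  Visit noise is added to post-baseline
    totals before rounding; totals are spread over the 21 items with item 1
    upweighted so that stem-depressed severity is controllable.
    """
    config.validate()
    if subjects is None:
        subjects = simulate_subjects(config)
    missing = set(subjects["subject_id"]) - set(genotypes.subjects)
    if missing:
        raise ValueError(f"subjects absent from genotypes: {sorted(missing)[:3]} ...")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    geno = genotypes.subset_subjects(list(subjects["subject_id"]))
    n = len(subjects)

    effect = np.zeros(n)
    for vid, beta in config.causal_effects.items():
        j = geno.variant_index(vid)
        dos = geno.calls[:, j].astype(float)
        dos[geno.calls[:, j] == MISSING] = 0.0
        effect += beta * dos
    effect += config.sex_improve_effect * (subjects["sex"].to_numpy() - 1)
    effect += config.age_improve_effect * (subjects["age"].to_numpy() - 44.0)

    baseline = np.minimum(14 + rng.poisson(config.baseline_extra_lam, size=n), MAX_TOTAL)
    improve = np.clip(rng.normal(config.improve_mean, config.improve_sd, size=n) + effect,
                      0.0, 1.0)

    weights = np.array(ITEM_MAX, dtype=float)
    weights[0] = config.item1_weight
    items = np.zeros((n, len(WEEKS), 21), dtype=np.int16)
    observed = np.ones((n, len(WEEKS)), dtype=bool)
    for wi, week in enumerate(WEEKS):
        frac = improve * (week / 8.0) ** config.time_exponent if week > 0 else 0.0
        total = baseline * (1.0 - frac)
        if week > 0 and config.visit_noise_sd > 0:
            total = total + rng.normal(0.0, config.visit_noise_sd, size=n)
        total = np.clip(np.rint(total), 0, MAX_TOTAL).astype(int)
        if week == 0:
            total = np.maximum(total, 14)  # inclusion criterion
        for i in range(n):
            items[i, wi, :] = allocate_items(total[i], weights)
    return subjects, HRSDPanel(list(subjects["subject_id"]), items, observed)


def inject_missingness(panel: HRSDPanel, config: SimulationConfig) -> HRSDPanel:
    """Remove whole post-baseline visits to emulate observed follow-up patterns.

    Each subject is assigned a pattern: all visits observed, exactly one of
    weeks 2/4/8 missing (uniform over the three), or two-plus missing (two
    visits with probability 0.8, all three with 0.2).  Week 0 is never
    removed.  Pattern probabilities come from ``config.missing_probs``.
    """
    config.validate()
    p0, p1, p2 = config.missing_probs
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    out = panel.copy()
    post = [1, 2, 3]  # week indices of weeks 2/4/8
    for i in range(out.n_subjects):
        u = rng.random()
        if u < p0:
            continue
        if u < p0 + p1:
            drop = [rng.choice(post)]
        else:
            k = 2 if rng.random() < 0.8 else 3
            drop = rng.choice(post, size=k, replace=False)
        for wi in drop:
            out.observed[i, wi] = False
            out.items[i, wi, :] = -1
    return out


# ---------------------------------------------------------------------------
# PLINK 1.9 binary I/O
# ---------------------------------------------------------------------------

def write_plink(genotypes: GenotypeMatrix, path_prefix: str | Path,
                subjects: pd.DataFrame | None = None,
                config: SimulationConfig | None = None) -> None:
    """Write bed/bim/fam (PLINK 1.9 binary, SNP-major).

    The bim A1 allele is the in-memory alt allele, so the 2-bit codes map as
    hom-A1 = 2 alt copies, het = 1, hom-A2 = 0, with PLINK's missing code for
    MISSING.  If ``subjects`` is given, its sex (1/2) and a phenotype of -9
    populate the fam file.  A sidecar ``.json`` records the seed and config
    hash when a :class:`SimulationConfig` is supplied.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sex = {}
    if subjects is not None:
        sex = dict(zip(subjects["subject_id"], subjects["sex"]))
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in genotypes.subjects:
            fh.write(f"{s}\t{s}\t0\t0\t{sex.get(s, 0)}\t-9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in genotypes.variants:
            fh.write(f"{v.chromosome}\t{v.id}\t0\t{v.position}\t{v.allele_alt}\t{v.allele_ref}\n")
    n = genotypes.n_subjects
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        buf = bytearray(n_bytes)
        for j in range(genotypes.n_variants):
            for k in range(n_bytes):
                buf[k] = 0
            col = genotypes.calls[:, j]
            for i in range(n):
                buf[i >> 2] |= _BED_ENCODE[int(col[i])] << ((i & 3) * 2)
            fh.write(bytes(buf))
    if config is not None:
        sidecar = {"seed": config.seed, "config_hash": config.config_hash()}
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_plink(path_prefix: str | Path) -> GenotypeMatrix:
    """Read bed/bim/fam written by :func:`write_plink` (or PLINK itself)."""
    prefix = Path(path_prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str)
    variants = [VariantInfo(id=r.id, chromosome=r.chrom, position=int(r.pos),
                            allele_ref=r.a2, allele_alt=r.a1)
                for r in bim.itertuples()]
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes {raw[:3]!r} "
                         "(expected PLINK 1.9 SNP-major)")
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != m * n_bytes:
        raise ValueError(f"{prefix}.bed payload of {payload.size} bytes inconsistent "
                         f"with {n} samples x {m} variants")
    payload = payload.reshape(m, n_bytes)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts) & 0b11  # (m, n_bytes, 4)
    calls = _BED_DECODE[codes.reshape(m, -1)[:, :n]].T.copy()
    return GenotypeMatrix(list(fam["iid"]), variants, calls)


# ---------------------------------------------------------------------------
# TSV phenotype I/O
# ---------------------------------------------------------------------------

_HRSD_COLUMNS = (["subject_id", "cohort", "sex", "age", "week"]
                 + [f"item{i:02d}" for i in range(1, 22)])


def write_hrsd(panel: HRSDPanel, subjects: pd.DataFrame, path: str | Path,
               config: SimulationConfig | None = None) -> None:
    """Write the HRSD panel as long-format TSV (one row per subject-week).

    Missing visits are written with item cells ``NA``.  Schema:
    subject_id, cohort, sex, age, week, item01..item21.
    """
    meta = subjects.set_index("subject_id")
    rows = []
    for i, sid in enumerate(panel.subjects):
        for wi, week in enumerate(WEEKS):
            row = [sid, meta.at[sid, "cohort"], int(meta.at[sid, "sex"]),
                   meta.at[sid, "age"], week]
            if panel.observed[i, wi]:
                row += [int(x) for x in panel.items[i, wi, :]]
            else:
                row += ["NA"] * 21
            rows.append(row)
    df = pd.DataFrame(rows, columns=_HRSD_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    if config is not None:
        sidecar = {"seed": config.seed, "config_hash": config.config_hash()}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_hrsd(path: str | Path) -> tuple[pd.DataFrame, HRSDPanel]:
    """Read a long-format HRSD TSV back into (subject table, panel)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    unknown = set(df.columns) - set(_HRSD_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in {path}: {sorted(unknown)}")
    missing_cols = set(_HRSD_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing columns in {path}: {sorted(missing_cols)}")
    item_cols = [f"item{i:02d}" for i in range(1, 22)]
    subjects = (df[["subject_id", "cohort", "sex", "age"]]
                .drop_duplicates("subject_id").reset_index(drop=True))
    subjects["sex"] = subjects["sex"].astype(int)
    sids = list(subjects["subject_id"])
    items = np.full((len(sids), len(WEEKS), 21), -1, dtype=np.int16)
    observed = np.zeros((len(sids), len(WEEKS)), dtype=bool)
    pos = {s: i for i, s in enumerate(sids)}
    for row in df.itertuples(index=False):
        i = pos[row.subject_id]
        wi = WEEKS.index(int(row.week))
        vals = [getattr(row, c) for c in item_cols]
        if all(pd.notna(v) for v in vals):
            items[i, wi, :] = [int(v) for v in vals]
            observed[i, wi] = True
        elif any(pd.notna(v) for v in vals):
            raise ValueError(f"partially missing visit for {row.subject_id} week {row.week}")
    return subjects, HRSDPanel(sids, items, observed)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a derived phenotype (or any result) table as TSV with NA sentinels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
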