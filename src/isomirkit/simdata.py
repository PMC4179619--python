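"""Synthetic small-RNA data: toy references, libraries, ground truth.

Generates everything the pipeline consumes, fully seeded: toy hairpins
with embedded matures and >= 3 nt flanks, and adapter-bearing FASTQ
libraries drawn from a known mixture of canonical / extended / trimmed
isoforms plus decoy reads.  The decoys reproduce the multi-modal
post-trimming length profile of a real small-RNA library: adapter-only
reads (mode 0), short degradation fragments peaking near 10 nt, tRNA-like
34 nt fragments, and full-length reads where adapter removal fails
(mode = read length).  A truth table of intended per-variant counts is
emitted so parameter-recovery tests can compare pipeline output against
construction.

The error model is substitution-only: the downstream assigner is exact,
so any substitution in the insert makes a read unassignable (or, rarely,
assignable to a neighbouring database variant), while indels would break
matching trivially and model nothing the pipeline could distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .readprep import ReadRecord
from .refdb import (
    HairpinRecord,
    MatureLocus,
    MatureRecord,
    VariantDB,
    locate_mature,
)

DNA = "ACGT"

#: Illumina TruSeq small-RNA 3' adapter (RA3) plus downstream primer bases,
#: long enough that insert+adapter always spans a 50 nt read.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCACATCACG"

#: read-share mixture of a typical small-RNA library: canonical ~60%,
#: 3' modifications ~30% (templated about twice the non-templated, with
#: adenylation the dominant and uridylation the second pure tail),
#: 3' trimming ~10%, 5' modifications ~0.5%
DEFAULT_MIXTURE = {
    "canonical": 0.60,
    "ext3_t": 0.20,
    "ext3_nt_A": 0.05,
    "ext3_nt_U": 0.02,
    "ext3_nt": 0.03,
    "trim3": 0.095,
    "ext5_t": 0.0025,
    "ext5_nt": 0.0025,
}

DEFAULT_DECOYS = {
    "adapter_only": 0.10,
    "short_fragment": 0.12,
    "trna_like": 0.10,
    "long_unclipped": 0.08,
}


class SimError(Exception):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Deterministic description of one simulated experiment.

    ``mixture`` maps variant classes (``canonical``, ``trim3``,
    ``ext5_t``, ``ext5_nt``, ``ext3_t``, ``ext3_nt``, or iso-group
    refined ``ext3_nt_A``...) to proportions of the miRNA-derived reads;
    ``decoy_fractions`` are fractions of ALL reads, the remainder being
    miRNA-derived.  ``variant_weights`` optionally overrides the uniform
    within-class choice with explicit per-variant weights.
    """

    seed: int = 1
    n_loci: int = 5
    #: canonical matures default to the modal 22 nt miRNA length so the
    #: simulated post-trimming histogram peaks at 22; widen for
    #: length-heterogeneous references
    mature_len: tuple[int, int] = (22, 22)
    flank_len: tuple[int, int] = (8, 15)
    paralog_dup: bool = False
    n_reads: int = 10_000
    read_length: int = 50
    adapter: str = DEFAULT_ADAPTER
    substitution_error_rate: float = 0.0
    mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    decoy_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DECOYS)
    )
    variant_weights: dict[str, float] | None = None

    def validate(self) -> None:
        if self.mature_len[0] < 18:
            raise SimError("mature_len below the 18 nt alignment minimum")
        if self.mature_len[0] > self.mature_len[1]:
            raise SimError("empty mature_len range")
        if self.flank_len[0] < 3:
            raise SimError("flanks must be >= 3 nt to template all extensions")
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise SimError("mixture proportions must sum to 1")
        decoy_total = sum(self.decoy_fractions.values())
        if decoy_total > 1.0 + 1e-9 or any(
            f < 0 for f in self.decoy_fractions.values()
        ):
            raise SimError("decoy fractions must be non-negative and sum to <= 1")
        if not 0 <= self.substitution_error_rate < 1:
            raise SimError("substitution_error_rate must be in [0, 1)")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


def make_toy_reference(
    config: SimConfig,
) -> tuple[list[MatureRecord], list[HairpinRecord], list[MatureLocus]]:
    """Random matures embedded in random hairpins, with ground-truth loci.

    Each mature occurs exactly once in exactly one hairpin (verified, the
    draw is retried otherwise); with ``paralog_dup`` the first mature is
    additionally embedded in a second hairpin with different flanks,
    mimicking a miRNA encoded at two genomic loci.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    for _attempt in range(50):
        matures: list[MatureRecord] = []
        hairpins: list[HairpinRecord] = []
        for i in range(config.n_loci):
            L = int(rng.integers(config.mature_len[0], config.mature_len[1] + 1))
            mseq = _random_seq(rng, L)
            f5 = _random_seq(rng, int(rng.integers(*config.flank_len)))
            f3 = _random_seq(rng, int(rng.integers(*config.flank_len)))
            matures.append(MatureRecord(f"syn-miR-{i + 1}-3p", f"SYN{i + 1:07d}", mseq))
            hairpins.append(HairpinRecord(f"syn-mir-{i + 1}", f5 + mseq + f3))
        if config.paralog_dup:
            m = matures[0]
            f5 = _random_seq(rng, int(rng.integers(*config.flank_len)))
            f3 = _random_seq(rng, int(rng.integers(*config.flank_len)))
            hairpins.append(HairpinRecord("syn-mir-1-2", f5 + m.sequence + f3))
        if len({m.sequence for m in matures}) < len(matures):
            continue
        ok = True
        for m in matures:
            expected = 2 if (config.paralog_dup and m is matures[0]) else 1
            hits = sum(hp.sequence.count(m.sequence) for hp in hairpins)
            if hits != expected:
                ok = False
                break
        if ok:
            loci = [
                locus for m in matures for locus in locate_mature(m, hairpins)
            ]
            return matures, hairpins, loci
    raise SimError("could not build a collision-free toy reference")


def _class_pool(db: VariantDB, key: str) -> list[str]:
    """Variant ids matching a mixture class key, restricted to variants
    whose sequence is unique in the database (so truth is recoverable)."""
    dup_ids = {vid for group in db.duplicate_groups for vid in group}
    pool = []
    for v in db.variants:
        if v.variant_id in dup_ids:
            continue
        if key == "canonical" and v.category == "canonical":
            pool.append(v.variant_id)
        elif key == "trim3" and v.category == "trim3":
            pool.append(v.variant_id)
        elif key in ("ext5_t", "ext5_nt", "ext3_t", "ext3_nt"):
            cat, origin = key.split("_")
            if v.category == cat and v.templated == (origin == "t"):
                pool.append(v.variant_id)
        elif key.startswith("ext3_nt_"):
            group = key.rsplit("_", 1)[1]
            if (
                v.category == "ext3"
                and not v.templated
                and v.pure
                and v.iso_group == group
            ):
                pool.append(v.variant_id)
    return sorted(pool)


def simulate_library(
    config: SimConfig, db: VariantDB
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Draw a seeded read library and its ground-truth count table.

    Each miRNA read is a variant sequence followed by the 3' adapter,
    truncated to the read length; decoys follow the configured length
    profile.  Substitution errors are applied uniformly per base AFTER
    the truth table is recorded, so truth counts are intended, pre-error
    counts.  Same config (incl. seed) => byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    # errors draw from their own stream so the structural draws -- and
    # with them the truth table -- are identical across error rates
    error_rng = np.random.default_rng(config.seed + 2)
    decoy_classes = sorted(config.decoy_fractions)
    decoy_p = [config.decoy_fractions[c] for c in decoy_classes]
    mirna_p = 1.0 - sum(decoy_p)
    class_names = decoy_classes + ["mirna"]
    class_probs = np.array(decoy_p + [mirna_p])
    mix_keys = sorted(config.mixture)
    mix_probs = np.array([config.mixture[k] for k in mix_keys])
    pools = {k: _class_pool(db, k) for k in mix_keys}
    for k, pool in pools.items():
        if not pool:
            raise SimError(f"mixture class {k!r} matches no unique-sequence variant")
    weights = config.variant_weights or {}
    pool_probs = {}
    for k, pool in pools.items():
        w = np.array([weights.get(vid, 1.0) for vid in pool], dtype=float)
        pool_probs[k] = w / w.sum()
    adapter = config.adapter
    rl = config.read_length
    reads: list[ReadRecord] = []
    truth: dict[str, int] = {}
    for i in range(config.n_reads):
        cls = class_names[rng.choice(len(class_names), p=class_probs)]
        if cls == "mirna":
            key = mix_keys[rng.choice(len(mix_keys), p=mix_probs)]
            pool = pools[key]
            vid = pool[rng.choice(len(pool), p=pool_probs[key])]
            insert = db.get(vid).sequence
            truth[vid] = truth.get(vid, 0) + 1
            seq = (insert + adapter)[:rl]
            if len(seq) < rl:  # very long insert + short adapter
                seq = seq + _random_seq(rng, rl - len(seq))
        elif cls == "adapter_only":
            seq = (adapter * ((rl // len(adapter)) + 1))[:rl]
        elif cls == "short_fragment":
            # degradation products, 6-17 nt, peaked at 10
            if rng.random() < 0.5:
                frag_len = 10
            else:
                frag_len = int(rng.integers(6, 18))
            seq = (_random_seq(rng, frag_len) + adapter)[:rl]
        elif cls == "trna_like":
            seq = (_random_seq(rng, 34) + adapter)[:rl]
        elif cls == "long_unclipped":
            seq = _random_seq(rng, rl)
        else:
            raise SimError(f"unknown decoy class {cls!r}")
        if config.substitution_error_rate > 0:
            arr = np.array(list(seq))
            hit = error_rng.random(len(arr)) < config.substitution_error_rate
            for j in np.nonzero(hit)[0]:
                choices = [b for b in DNA if b != arr[j]]
                arr[j] = choices[error_rng.integers(3)]
            seq = "".join(arr)
        reads.append(ReadRecord(f"sim_{i:06d}", seq, "I" * len(seq)))
    return reads, truth


def write_truth_table(truth: dict[str, int], path) -> None:
    with open(path, "w") as handle:
        handle.write("variant_id\tintended_count\n")
        for vid in sorted(truth):
            handle.write(f"{vid}\t{truth[vid]}\n")


def write_config_echo(config: SimConfig, path) -> None:
    """Echo the simulation parameters as a plain key=value file."""
    with open(path, "w") as handle:
        for key, value in sorted(vars(config).items()):
            handle.write(f"{key}={value!r}\n")
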