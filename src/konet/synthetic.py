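"""Synthetic fixtures with known ground truth for every pipeline stage.

Two generators cover the pipeline's inputs:

* :func:`generate_reference` draws a random reaction table and returns it
  together with the edge set computed by :func:`brute_force_edges`, an
  exhaustive O(|reactions|^2) enumeration kept deliberately independent of
  the indexed construction in :mod:`konet.reference_model` so it can serve
  as an oracle.

* :func:`generate_profiles` simulates per-sample annotation profiles.
  Reads are drawn from a per-state KO multinomial with a lognormal
  rank-abundance base vector; in "state1" the planted KO's probability is
  scaled by ``2**planted_log2_fold`` and the vector renormalized.  A
  configured fraction of reads hits a multi-KO reference sequence and a
  fraction produces two tied best hits, exercising both even-split
  guidelines of the abundance estimator.  Both constructions pick the extra
  KO from the same state distribution, which keeps the expected split
  weight of every KO equal to its true probability, so the estimator
  remains unbiased under splitting.

All randomness flows from a single integer seed; per-sample substreams use
fixed offsets so outputs are reproducible across machines.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation_io import AnnotationProfile, AnnotationRecord, write_annotation_profile
from .errors import ValidationError
from .reference_model import Reaction, write_reaction_table

STATE1, STATE2 = "state1", "state2"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe a small two-state gut-microbiome-like comparison:
    50 enzyme families, 20 samples per state at 10^4 annotated reads each
    (deep enough that per-sample abundance noise is ~1%), 10% of reads
    hitting multi-KO references and 10% producing tied best hits, and one
    planted KO with a 2-fold abundance shift in state1.
    """

    n_kos: int = 50
    n_compounds: int = 30
    n_reactions: int = 60
    reversible_fraction: float = 0.2
    n_samples_per_state: int = 20
    n_reads: int = 10_000
    multi_ko_fraction: float = 0.1
    tie_fraction: float = 0.1
    planted_ko: str | None = "K00001"
    planted_log2_fold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_kos", "n_compounds", "n_samples_per_state", "n_reads"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_reactions < 0:
            raise ValidationError("n_reactions must be >= 0")
        for name in ("reversible_fraction", "multi_ko_fraction", "tie_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.multi_ko_fraction + self.tie_fraction > 1.0:
            raise ValidationError("multi_ko_fraction + tie_fraction must be <= 1")

    @property
    def ko_universe(self) -> list[str]:
        return [f"K{i:05d}" for i in range(1, self.n_kos + 1)]

    @property
    def compound_universe(self) -> list[str]:
        return [f"C{i:05d}" for i in range(1, self.n_compounds + 1)]


def brute_force_edges(
    reactions: list[Reaction],
    exclude_compounds: frozenset[str] = frozenset(),
    allow_self_loops: bool = False,
) -> set[tuple[str, str]]:
    """Exhaustive edge enumeration over all ordered reaction pairs.

    For every ordered pair (r1, r2) and every shared compound c (effective
    product of r1, effective substrate of r2, not excluded), all KO pairs
    (a in r1, b in r2) become edges.  Quadratic and index-free on purpose:
    this is the oracle the fast construction is tested against.
    """
    edges: set[tuple[str, str]] = set()
    for r1 in reactions:
        for r2 in reactions:
            shared = (r1.effective_products & r2.effective_substrates) - exclude_compounds
            if not shared:
                continue
            for a in r1.ko_ids:
                for b in r2.ko_ids:
                    if a == b and not allow_self_loops:
                        continue
                    edges.add((a, b))
    return edges


def generate_reference(
    config: SimulationConfig,
) -> tuple[list[Reaction], set[tuple[str, str]]]:
    """Draw a random reaction table plus its oracle edge set.

    Each reaction gets 1-2 catalyzing KOs and 1-2 substrates and products
    sampled without overlap within the reaction; reversibility is Bernoulli
    with ``reversible_fraction``.
    """
    if config.n_compounds < 2:
        raise ValidationError("need at least 2 compounds to form a reaction")
    rng = np.random.default_rng([config.seed, 1])
    kos = config.ko_universe
    compounds = config.compound_universe
    reactions: list[Reaction] = []
    for i in range(config.n_reactions):
        n_ko = 1 + int(rng.random() < 0.3)
        r_kos = rng.choice(len(kos), size=min(n_ko, len(kos)), replace=False)
        n_sub = 1 + int(rng.random() < 0.5)
        n_prod = 1 + int(rng.random() < 0.5)
        while n_sub + n_prod > len(compounds):
            if n_prod > 1:
                n_prod -= 1
            else:
                n_sub -= 1
        picked = rng.choice(len(compounds), size=n_sub + n_prod, replace=False)
        reactions.append(
            Reaction(
                reaction_id=f"R{i + 1:05d}",
                ko_ids=frozenset(kos[j] for j in r_kos),
                substrate_ids=frozenset(compounds[j] for j in picked[:n_sub]),
                product_ids=frozenset(compounds[j] for j in picked[n_sub:]),
                reversible=bool(rng.random() < config.reversible_fraction),
            )
        )
    # the planted KO must be able to appear in networks: give it a reaction
    if (
        config.planted_ko is not None
        and reactions
        and all(config.planted_ko not in r.ko_ids for r in reactions)
    ):
        first = reactions[0]
        reactions[0] = dataclasses.replace(
            first, ko_ids=first.ko_ids | {config.planted_ko}
        )
    return reactions, brute_force_edges(reactions)


def _state_probabilities(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Lognormal base abundances; planted KO scaled up in state1."""
    rng = np.random.default_rng([config.seed, 0])
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_kos)
    base /= base.sum()
    p2 = base
    p1 = base.copy()
    if config.planted_ko is not None:
        kos = config.ko_universe
        if config.planted_ko not in kos:
            raise ValidationError(
                f"planted_ko {config.planted_ko!r} not among the {config.n_kos} KOs"
            )
        k = kos.index(config.planted_ko)
        p1[k] *= 2.0 ** config.planted_log2_fold
        p1 = p1 / p1.sum()
    return {STATE1: p1, STATE2: p2}


def _sample_profile(
    config: SimulationConfig, sample_id: str, probs: np.ndarray, rng: np.random.Generator
) -> AnnotationProfile:
    kos = config.ko_universe
    k1 = rng.choice(config.n_kos, size=config.n_reads, p=probs)
    k2 = rng.choice(config.n_kos, size=config.n_reads, p=probs)
    cat = rng.random(config.n_reads)
    exponents = rng.integers(5, 50, size=config.n_reads)
    mantissas = np.round(rng.uniform(1.0, 9.99, size=config.n_reads), 2)

    records: list[AnnotationRecord] = []
    for i in range(config.n_reads):
        read_id = f"{sample_id}_r{i:06d}"
        a, b = kos[k1[i]], kos[k2[i]]
        e = float(f"{mantissas[i]}e-{exponents[i]}")
        if cat[i] < config.tie_fraction and a != b:
            # two best hits at an identical e-value string
            records.append(AnnotationRecord(read_id, f"ref_{a}", e, (a,)))
            records.append(AnnotationRecord(read_id, f"ref_{b}", e, (b,)))
        elif cat[i] < config.tie_fraction + config.multi_ko_fraction and a != b:
            lo, hi = sorted((a, b))
            records.append(AnnotationRecord(read_id, f"ref_{lo}_{hi}", e, (lo, hi)))
        else:
            records.append(AnnotationRecord(read_id, f"ref_{a}", e, (a,)))
    return AnnotationProfile(sample_id=sample_id, records=records)


def generate_profiles(
    config: SimulationConfig,
) -> tuple[list[AnnotationProfile], dict[str, str], dict]:
    """Simulate annotation profiles for both states.

    Returns the profiles, the sample -> state label map, and a ground-truth
    dict carrying the per-state KO probability vectors, the planted effect
    and its true log2 odds ratio.
    """
    probs = _state_probabilities(config)
    profiles: list[AnnotationProfile] = []
    state_labels: dict[str, str] = {}
    for si, state in enumerate((STATE1, STATE2)):
        for j in range(config.n_samples_per_state):
            sample_id = f"{state}_s{j:02d}"
            rng = np.random.default_rng([config.seed, 2, si, j])
            profiles.append(_sample_profile(config, sample_id, probs[state], rng))
            state_labels[sample_id] = state

    truth: dict = {
        "ko_ids": config.ko_universe,
        "state1_probs": probs[STATE1].tolist(),
        "state2_probs": probs[STATE2].tolist(),
        "planted_ko": config.planted_ko,
        "planted_log2_fold": config.planted_log2_fold,
    }
    if config.planted_ko is not None:
        k = config.ko_universe.index(config.planted_ko)
        p, q = probs[STATE1][k], probs[STATE2][k]
        truth["true_log2_or"] = math.log2((p / (1 - p)) / (q / (1 - q)))
    return profiles, state_labels, truth


def write_fixture(config: SimulationConfig, outdir: str | Path) -> dict:
    """Materialize a complete fixture directory.

    Writes ``reactions.tsv``, one annotation TSV per sample, and a
    ``truth.json`` sidecar (state labels, sample files, true probability
    vectors, planted effect, oracle edges).  Returns the sidecar dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reactions, oracle_edges = generate_reference(config)
    write_reaction_table(reactions, outdir / "reactions.tsv")
    profiles, state_labels, truth = generate_profiles(config)
    sample_files = {}
    for p in profiles:
        fname = f"{p.sample_id}.tsv"
        write_annotation_profile(p, outdir / fname)
        sample_files[p.sample_id] = fname
    sidecar = {
        "config": dataclasses.asdict(config),
        "state_labels": state_labels,
        "sample_files": sample_files,
        "oracle_edges": sorted(list(e) for e in oracle_edges),
        **truth,
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1), encoding="utf-8")
    return sidecar
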