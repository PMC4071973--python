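"""Synthetic band matrices with planted population structure.

The generator emulates the data structure of a dominant-marker fingerprinting
study: a small strain panel scored over primer combinations that each yield a
handful of bands, a share of which are monomorphic across the panel. The
evolutionary model is deliberately minimal — no coalescent, no mutation
clock:

1. each *ancestor* (planted cluster) draws a binary ancestral profile over
   the polymorphic bands (Bernoulli ``ancestral_presence_prob``, redrawn per
   ancestor); monomorphic bands are fixed present in everyone;
2. optional *subgroups* within an ancestor perturb its profile at a fixed
   number of subgroup-specific bands (all members of the subgroup share the
   perturbation);
3. each strain copies its (sub)group profile and applies independent
   per-band state flips with probability ``flip_probability`` — the noise
   that keeps strains of one cluster similar but not identical.

Every draw goes through one seeded generator, so identical configs produce
bit-identical matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from trapdiv.errors import ValidationError
from trapdiv.matrix_io import BandDef, MarkerMatrix, load_table1_fixture

_ANCESTOR_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic band-matrix draw.

    ``ancestor_weights`` are cluster-size fractions (sum to 1; converted to
    integer counts by largest remainder). ``subgroup_split`` optionally nests
    weight tuples per ancestor; ``None`` for an unstructured ancestor.
    ``monomorphic_fraction`` of all bands are fixed present in every strain
    and receive no noise. ``subgroup_flip_count`` polymorphic bands are
    flipped, as a block, in each non-largest subgroup of an ancestor.
    """

    n_strains: int
    ancestor_weights: tuple[float, ...]
    primer_band_counts: tuple[int, ...]
    primer_names: tuple[str, ...] | None = None
    subgroup_split: tuple[tuple[float, ...] | None, ...] | None = None
    monomorphic_fraction: float = 0.30
    flip_probability: float = 0.05
    ancestral_presence_prob: float = 0.5
    subgroup_flip_count: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValidationError("n_strains must be >= 2")
        if not self.ancestor_weights or abs(sum(self.ancestor_weights) - 1.0) > 1e-9:
            raise ValidationError("ancestor_weights must sum to 1")
        if any(w < 0 for w in self.ancestor_weights):
            raise ValidationError("ancestor_weights must be non-negative")
        if not self.primer_band_counts or any(
            c < 1 for c in self.primer_band_counts
        ):
            raise ValidationError("primer_band_counts must all be >= 1")
        for name, p in (
            ("monomorphic_fraction", self.monomorphic_fraction),
            ("flip_probability", self.flip_probability),
            ("ancestral_presence_prob", self.ancestral_presence_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {p}")
        if self.subgroup_flip_count < 0:
            raise ValidationError("subgroup_flip_count must be >= 0")
        if self.subgroup_split is not None:
            if len(self.subgroup_split) != len(self.ancestor_weights):
                raise ValidationError(
                    "subgroup_split must have one entry per ancestor"
                )
            for sw in self.subgroup_split:
                if sw is None:
                    continue
                if abs(sum(sw) - 1.0) > 1e-9 or any(w < 0 for w in sw):
                    raise ValidationError(
                        "subgroup weights must be non-negative and sum to 1"
                    )
        if self.primer_names is not None and len(self.primer_names) != len(
            self.primer_band_counts
        ):
            raise ValidationError(
                "primer_names must match primer_band_counts in length"
            )

    @property
    def n_bands(self) -> int:
        return int(sum(self.primer_band_counts))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        for key in ("ancestor_weights", "primer_band_counts", "primer_names"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if raw.get("subgroup_split") is not None:
            raw["subgroup_split"] = tuple(
                tuple(sw) if sw is not None else None
                for sw in raw["subgroup_split"]
            )
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Ground-truth labels and ancestral profiles behind a simulated matrix."""

    cluster_labels: dict[str, int]
    subgroup_labels: dict[str, str]
    ancestral_profiles: np.ndarray  # n_ancestors x n_bands

    def write_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["strain", "cluster", "subgroup"])
            for strain in self.cluster_labels:
                w.writerow(
                    [strain, self.cluster_labels[strain], self.subgroup_labels[strain]]
                )


def _largest_remainder(weights, total: int) -> list[int]:
    raw = [w * total for w in weights]
    counts = [int(np.floor(r)) for r in raw]
    short = total - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # biggest remainder first
    for idx in order[:short]:
        counts[idx] += 1
    return counts


def simulate_matrix(c: SimulationConfig) -> tuple[MarkerMatrix, SyntheticTruth]:
    """Draw one band matrix plus its ground truth from a config.

    Deterministic given the config (including its seed). Flip noise and
    subgroup perturbations touch polymorphic bands only; bands designated
    monomorphic stay present in every strain.
    """
    rng = np.random.default_rng(c.seed)
    n_bands = c.n_bands
    n_anc = len(c.ancestor_weights)

    primer_names = c.primer_names or tuple(
        f"P{i + 1:02d}" for i in range(len(c.primer_band_counts))
    )
    bands: list[BandDef] = []
    for pname, count in zip(primer_names, c.primer_band_counts):
        sizes = np.sort(
            rng.integers(10, 211, size=count) * 10
        )[::-1]  # 100..2100 bp, largest fragment first as on a gel
        for b in range(count):
            bands.append(BandDef(pname, f"b{b + 1}", int(sizes[b])))

    n_mono = int(round(c.monomorphic_fraction * n_bands))
    mono_idx = rng.choice(n_bands, size=n_mono, replace=False)
    is_mono = np.zeros(n_bands, dtype=bool)
    is_mono[mono_idx] = True
    poly_idx = np.flatnonzero(~is_mono)

    # ancestral profiles
    profiles = np.ones((n_anc, n_bands), dtype=np.int8)
    for a in range(n_anc):
        profiles[a, poly_idx] = (
            rng.random(poly_idx.size) < c.ancestral_presence_prob
        ).astype(np.int8)

    anc_counts = _largest_remainder(c.ancestor_weights, c.n_strains)

    # subgroup profiles: non-largest subgroups get a block of private flips
    group_profiles: list[np.ndarray] = []
    group_subgroup: list[str] = []
    group_ancestor: list[int] = []
    group_counts: list[int] = []
    for a, n_a in enumerate(anc_counts):
        letter = _ANCESTOR_LETTERS[a]
        split = None
        if c.subgroup_split is not None:
            split = c.subgroup_split[a]
        if split is None or n_a == 0:
            group_profiles.append(profiles[a].copy())
            group_subgroup.append(letter)
            group_ancestor.append(a)
            group_counts.append(n_a)
            continue
        sub_counts = _largest_remainder(split, n_a)
        largest = int(np.argmax(sub_counts))
        for s, n_s in enumerate(sub_counts):
            prof = profiles[a].copy()
            if s != largest and c.subgroup_flip_count > 0 and n_s > 0:
                if c.subgroup_flip_count > poly_idx.size:
                    raise ValidationError(
                        "subgroup_flip_count exceeds polymorphic band count"
                    )
                flips = rng.choice(
                    poly_idx, size=c.subgroup_flip_count, replace=False
                )
                prof[flips] = 1 - prof[flips]
            group_profiles.append(prof)
            group_subgroup.append(f"{letter}{s + 1}")
            group_ancestor.append(a)
            group_counts.append(n_s)

    width = max(2, len(str(c.n_strains)))
    strain_ids = [f"S{i + 1:0{width}d}" for i in range(c.n_strains)]
    values = np.zeros((c.n_strains, n_bands), dtype=np.int8)
    cluster_labels: dict[str, int] = {}
    subgroup_labels: dict[str, str] = {}

    i = 0
    for prof, sub, anc, count in zip(
        group_profiles, group_subgroup, group_ancestor, group_counts
    ):
        for _ in range(count):
            strain = prof.copy()
            flips = rng.random(poly_idx.size) < c.flip_probability
            cols = poly_idx[flips]
            strain[cols] = 1 - strain[cols]
            values[i] = strain
            cluster_labels[strain_ids[i]] = anc + 1
            subgroup_labels[strain_ids[i]] = sub
            i += 1

    matrix = MarkerMatrix(strain_ids, bands, values)
    truth = SyntheticTruth(cluster_labels, subgroup_labels, profiles)
    return matrix, truth


def default_paper_config(seed: int = 1234) -> SimulationConfig:
    """Default study conditions: a 20-strain panel over the packaged
    28-primer architecture.

    Two planted ancestors weighted 18/20 and 2/20, the larger split into
    nested subgroups of 2, 14 and 2 strains; per-primer band counts taken
    from the packaged reference panel (288 bands total, ~70% designated
    polymorphic); flip probability 0.05.
    """
    fixture = load_table1_fixture()
    return SimulationConfig(
        n_strains=20,
        ancestor_weights=(18 / 20, 2 / 20),
        primer_band_counts=tuple(r.total_bands for r in fixture.rows),
        primer_names=tuple(r.primer_name for r in fixture.rows),
        subgroup_split=((2 / 18, 14 / 18, 2 / 18), None),
        monomorphic_fraction=0.30,
        flip_probability=0.05,
        ancestral_presence_prob=0.5,
        subgroup_flip_count=15,
        seed=seed,
    )
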