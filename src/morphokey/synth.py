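"""Synthetic measurement tables and key matrices.

The measurement generator draws log-normal measurements with a shared
per-specimen size factor, group-specific shape means (planted ratio
contrasts), optional allometric slopes and i.i.d. log-scale noise:

    value(i, j) = exp(base_j + offset_{g(i), j} + slope_j * s_i + eps_ij)

with ``s_i ~ N(0, size_sd)`` and ``eps_ij ~ N(0, noise_sd)``.  Equal
slopes model pure isometry (size cancels from every ratio); a +delta /
-delta offset pair on two variables plants a known best ratio for the
extractor to recover.  Defaults mirror a typical two-species
delimitation study: two groups of 30 specimens, the standard
28-variable selection, about 10% joint size variation and 2% residual
log-scale noise.

The key-matrix generator produces random categorical/quantitative
descriptor matrices with controlled polymorphism and unknown-cell
rates, optionally guaranteeing pairwise-distinct taxon signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from morphokey.key_engine import (
    UNKNOWN,
    Descriptor,
    KeyMatrix,
    KeyMatrixError,
    TaxonDescription,
)
from morphokey.measurement_io import MeasurementTable
from morphokey.mra import DEFAULT_SHAPE_VARIABLES


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic measurement table.

    ``base_log_means`` defaults to log measurements spread over a
    realistic micrometre scale (about 80–1500 µm).  ``group_offsets``
    maps group label -> per-variable log offsets; ``planted_pair``
    plants a +delta/-delta contrast on two named variables in the
    second group, defining a known best ratio.
    """

    groups: tuple[tuple[str, int], ...] = (("A", 30), ("B", 30))
    variables: tuple[str, ...] = DEFAULT_SHAPE_VARIABLES
    base_log_means: Sequence[float] | None = None
    group_offsets: Mapping[str, Sequence[float]] | None = None
    planted_pair: tuple[str, str] | None = None
    planted_delta: float = 0.0
    allometry_slopes: Sequence[float] | None = None
    size_sd: float = 0.1
    noise_sd: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.groups):
            raise ValueError("each group needs at least 1 specimen")
        if self.noise_sd < 0 or self.size_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        p = len(self.variables)
        if self.base_log_means is None:
            # spread typical body-part sizes over ~80-1500 um, fixed layout
            self.base_log_means = np.linspace(np.log(80.0), np.log(1500.0), p)
        self.base_log_means = np.asarray(self.base_log_means, dtype=float)
        if self.allometry_slopes is None:
            self.allometry_slopes = np.ones(p)
        self.allometry_slopes = np.asarray(self.allometry_slopes, dtype=float)

    def offsets_for(self, group: str) -> np.ndarray:
        p = len(self.variables)
        off = np.zeros(p)
        if self.group_offsets and group in self.group_offsets:
            off = off + np.asarray(self.group_offsets[group], dtype=float)
        if self.planted_pair is not None and group == self.groups[-1][0]:
            i = self.variables.index(self.planted_pair[0])
            j = self.variables.index(self.planted_pair[1])
            off = off.copy()
            off[i] += self.planted_delta
            off[j] -= self.planted_delta
        return off


def simulate_measurements(spec: SyntheticSpec) -> MeasurementTable:
    """Draw a measurement table from the generative model (reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    ids = []
    species = []
    for label, n in spec.groups:
        off = spec.offsets_for(label)
        for k in range(n):
            s = rng.normal(0.0, spec.size_sd)
            eps = rng.normal(0.0, spec.noise_sd, size=len(spec.variables))
            logv = spec.base_log_means + off + spec.allometry_slopes * s + eps
            rows.append(np.exp(logv))
            ids.append(f"{label}-{k + 1:03d}")
            species.append(label)
    data = pd.DataFrame(rows, index=ids, columns=list(spec.variables))
    return MeasurementTable(
        data=data,
        species=pd.Series(species, index=ids),
        side=pd.Series(["left"] * len(ids), index=ids),
    )


def simulate_key_matrix(
    n_taxa: int,
    n_descriptors: int,
    polymorphism_rate: float = 0.2,
    unknown_rate: float = 0.1,
    quantitative_fraction: float = 0.25,
    distinct: bool = False,
    seed: int | None = None,
) -> KeyMatrix:
    """Random taxa x descriptors key matrix.

    ``polymorphism_rate`` is the chance a categorical cell carries more
    than one state; ``unknown_rate`` the chance any cell is unknown.
    With ``distinct=True`` the generator redraws duplicated taxon
    descriptions (raising :class:`KeyMatrixError` when the descriptor
    space is too small to tell every taxon apart).
    """
    if n_taxa < 1 or n_descriptors < 1:
        raise ValueError("counts must be >= 1")
    for rate in (polymorphism_rate, unknown_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    descriptors = []
    for d in range(n_descriptors):
        if rng.random() < quantitative_fraction:
            descriptors.append(
                Descriptor(
                    name=f"q{d + 1}",
                    kind="quantitative",
                    unit="um",
                    weight=int(rng.integers(1, 6)),
                )
            )
        else:
            n_states = int(rng.integers(2, 5))
            descriptors.append(
                Descriptor(
                    name=f"c{d + 1}",
                    kind="categorical",
                    states=tuple(f"s{i + 1}" for i in range(n_states)),
                    weight=int(rng.integers(1, 6)),
                )
            )

    def draw_cell(d: Descriptor):
        if rng.random() < unknown_rate:
            return UNKNOWN
        if d.kind == "categorical":
            if rng.random() < polymorphism_rate and len(d.states) > 2:
                k = int(rng.integers(2, len(d.states)))
            elif rng.random() < polymorphism_rate:
                k = 2
            else:
                k = 1
            return frozenset(rng.choice(d.states, size=k, replace=False))
        # quantitative: interval on a coarse grid so ranges overlap sometimes
        lo = float(rng.integers(0, 8)) * 10.0
        hi = lo + float(rng.integers(1, 4)) * 10.0
        return (lo, hi)

    def signature(desc: dict):
        return tuple(
            tuple(sorted(v)) if isinstance(v, frozenset) else v
            for v in (desc[d.name] for d in descriptors)
        )

    def can_eliminate(a: dict, b: dict) -> bool:
        # does taxon a possess an observation (from its own cells) that
        # rules taxon b out on some descriptor?
        for d in descriptors:
            ca, cb = a[d.name], b[d.name]
            if ca == UNKNOWN or cb == UNKNOWN:
                continue
            if d.kind == "categorical":
                if set(ca) - set(cb):
                    return True
            else:
                if not (cb[0] <= ca[0] and ca[1] <= cb[1]):
                    return True
        return False

    taxa = []
    accepted: list[dict] = []
    seen: set = set()
    max_redraws = 200
    for t in range(n_taxa):
        desc = {d.name: draw_cell(d) for d in descriptors}
        if distinct:
            tries = 0
            # a unique signature must also be mutually separable from every
            # accepted taxon, otherwise no identification path can isolate it
            while signature(desc) in seen or any(
                not can_eliminate(desc, prev) or not can_eliminate(prev, desc)
                for prev in accepted
            ):
                tries += 1
                if tries > max_redraws:
                    raise KeyMatrixError(
                        "cannot generate pairwise-distinct descriptions: "
                        "descriptor state space too small"
                    )
                desc = {d.name: draw_cell(d) for d in descriptors}
            seen.add(signature(desc))
            accepted.append(desc)
        taxa.append(TaxonDescription(name=f"taxon-{t + 1:02d}", description=desc))
    return KeyMatrix(descriptors=tuple(descriptors), taxa=tuple(taxa))
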