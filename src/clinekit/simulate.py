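"""Synthetic hybrid-zone data with the statistical structure the analysis assumes.

Three generators cover every input the pipeline consumes:

* :func:`simulate_zone` — per-locus transect datasets: allele counts drawn
  binomially at each population from a true cline (the sampling model the
  binomial likelihood assumes; no spatial autocorrelation or drift beyond
  binomial noise).
* :func:`simulate_ecotype_panel` — two fixed-ecotype diploid panels with
  Hardy–Weinberg genotypes at given allele frequencies (emulating, e.g., a
  267-individual red panel and a 107-individual yellow panel).
* :func:`simulate_f2` — two-locus F2 intercross gametes with recombination
  fraction r.

All generators are pure functions of (config, seed); the seed is recorded
in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fitting import ClineDataset, PopulationSample
from .model import ClineParams, cline_frequency
from .popgen import F2CrossCounts, GenotypePanel

__all__ = ["ZoneSimConfig", "simulate_zone", "simulate_ecotype_panel", "simulate_f2"]


@dataclass
class ZoneSimConfig:
    """Sampling design of a simulated hybrid-zone transect.

    One true :class:`ClineParams` per locus, shared population positions
    (km), and the number of allele copies sampled per population (scalar or
    per-population sequence).
    """

    loci: Mapping[str, ClineParams]
    positions: Sequence[float]
    n_alleles: object = 80
    seed: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("population positions must be finite")
        n = np.broadcast_to(np.asarray(self.n_alleles, dtype=int), self.positions.shape).copy()
        if np.any(n < 0):
            raise ValidationError("n_alleles must be non-negative")
        self.n_alleles = n
        if not self.loci:
            raise ValidationError("at least one locus is required")


def simulate_zone(config: ZoneSimConfig) -> dict:
    """Draw one ClineDataset per locus: k_i ~ Binomial(n_i, p(x_i | true params)).

    A single RNG stream (seeded from config.seed) is shared across loci, so
    identical configs give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    out = {}
    for locus, params in config.loci.items():
        p = np.clip(cline_frequency(config.positions, params), 0.0, 1.0)
        k = rng.binomial(config.n_alleles, p)
        samples = tuple(
            PopulationSample(population_id=f"pop{i + 1:02d}", x=float(x), n=int(n), k=int(kk))
            for i, (x, n, kk) in enumerate(zip(config.positions, config.n_alleles, k))
        )
        out[locus] = ClineDataset(
            locus=locus,
            samples=samples,
            meta={"seed": config.seed, "true_params": params.as_dict()},
        )
    return out


def simulate_ecotype_panel(
    freq_A: float,
    freq_B: float,
    n_A: int,
    n_B: int,
    seed: int = 0,
    *,
    loci: Sequence[str] = ("L1",),
    group_labels: Sequence[str] = ("red", "yellow"),
) -> GenotypePanel:
    """Two-group diploid panel with Hardy–Weinberg genotypes.

    Each individual's R-allele dosage at each locus is Binomial(2, freq) at
    its group's frequency.  ``freq_A`` / ``freq_B`` may be scalars (shared
    across loci) or mappings locus -> frequency.
    """

    def freq_for(freq, locus):
        f = float(freq[locus]) if isinstance(freq, Mapping) else float(freq)
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"allele frequency {f} is outside [0, 1]")
        return f

    if n_A < 0 or n_B < 0:
        raise ValidationError("panel sizes must be non-negative")
    rng = np.random.default_rng(seed)
    ga, gb = group_labels
    records = []
    for group, n, freq in ((ga, n_A, freq_A), (gb, n_B, freq_B)):
        dosages = {
            locus: rng.binomial(2, freq_for(freq, locus), size=n) for locus in loci
        }
        for i in range(n):
            records.append(
                (f"{group}_{i + 1:04d}", group, group, {l: float(dosages[l][i]) for l in loci})
            )
    panel = GenotypePanel.from_records(records)
    panel.data.attrs["seed"] = seed
    return panel


def simulate_f2(r: float, n: int, seed: int = 0):
    """Two-locus F2 intercross: each individual receives two gametes, each
    independently recombinant with probability r.

    Returns (F2CrossCounts, genotype table).  ``n_recombinant`` counts
    recombinant gametes (the single-recombinant-gamete convention used to
    form r = n_recombinant / 2N).  The genotype table has the R-allele
    dosage at each locus plus the per-individual recombinant-gamete count.
    """
    if not 0.0 <= r <= 0.5:
        raise ValidationError("recombination fraction r must lie in [0, 0.5]")
    if n < 0:
        raise ValidationError("n must be non-negative")
    rng = np.random.default_rng(seed)
    # F1 gamete: allele at locus 1 uniform, locus 2 equal unless recombinant
    allele1 = rng.integers(0, 2, size=(n, 2))  # 1 = R
    rec = rng.random(size=(n, 2)) < r
    allele2 = np.where(rec, 1 - allele1, allele1)
    table = pd.DataFrame(
        {
            "locus1": allele1.sum(axis=1),
            "locus2": allele2.sum(axis=1),
            "recombinant_gametes": rec.sum(axis=1),
        },
        index=pd.RangeIndex(n, name="individual"),
    )
    table.attrs["seed"] = seed
    counts = F2CrossCounts(n_individuals=n, n_recombinant=int(rec.sum()))
    return counts, table
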