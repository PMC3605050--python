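"""Readers and writers for the pipeline's file formats.

Frequency tables are TSV/CSV files with one row per population along the
transect: required columns ``population`` and ``distance_km``, then per
locus either a count pair ``{locus}_n`` / ``{locus}_k`` or a frequency
column ``{locus}_freq`` combined with a shared ``n`` column (counts are
formed as k = round(freq * n); the rounding is recorded in the dataset
metadata).  Fit results serialize to JSON (with the dataset embedded, so a
comparison run needs only the fit files); comparison results to a TSV
matrix plus JSON summary.  All writers use stable ordering for diffability.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from ._version import __version__
from .errors import ValidationError
from .fitting import ClineDataset, ClineFitResult, ModelSpec, PopulationSample, SupportInterval
from .geography import Locality
from .model import ClineParams

__all__ = [
    "read_frequency_table",
    "write_frequency_table",
    "write_fit_json",
    "read_fit_json",
    "read_coastline",
    "read_localities",
    "read_vcf_panel",
    "file_sha256",
]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _sep_for(path, sep):
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_frequency_table(path, *, sep=None) -> dict:
    """Parse a per-population frequency/count table into one ClineDataset
    per locus.  Malformed rows are rejected with their file line number
    (header = line 1)."""
    sep = _sep_for(path, sep)
    df = pd.read_csv(path, sep=sep)
    required = {"population", "distance_km"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"frequency table is missing required columns: {sorted(missing)}")

    count_loci = sorted(
        c[:-2] for c in df.columns if c.endswith("_n") and f"{c[:-2]}_k" in df.columns
    )
    freq_loci = sorted(c[:-5] for c in df.columns if c.endswith("_freq"))
    if freq_loci and "n" not in df.columns:
        raise ValidationError(
            "frequency-dialect columns present but no 'n' column to form counts from"
        )
    if not count_loci and not freq_loci:
        raise ValidationError("no locus columns found ({locus}_n/{locus}_k or {locus}_freq)")

    datasets = {}
    for locus in count_loci:
        samples = []
        for idx, row in df.iterrows():
            line = idx + 2
            n, k = row[f"{locus}_n"], row[f"{locus}_k"]
            if pd.isna(n) or pd.isna(k) or n != int(n) or k != int(k):
                raise ValidationError(f"line {line}: locus {locus!r} counts must be integers")
            if k > n:
                raise ValidationError(f"line {line}: locus {locus!r} has k > n for population {row['population']!r}")
            samples.append(
                PopulationSample(str(row["population"]), float(row["distance_km"]), int(n), int(k))
            )
        datasets[locus] = ClineDataset(locus=locus, samples=tuple(samples))
    for locus in freq_loci:
        samples = []
        rounded = []
        for idx, row in df.iterrows():
            line = idx + 2
            freq, n = row[f"{locus}_freq"], row["n"]
            if pd.isna(freq) or not 0.0 <= freq <= 1.0:
                raise ValidationError(f"line {line}: locus {locus!r} frequency must lie in [0, 1]")
            if pd.isna(n) or n != int(n) or n < 0:
                raise ValidationError(f"line {line}: 'n' must be a non-negative integer")
            k = int(round(freq * n))
            if abs(k - freq * n) > 1e-9:
                rounded.append(str(row["population"]))
            samples.append(
                PopulationSample(str(row["population"]), float(row["distance_km"]), int(n), k)
            )
        datasets[locus] = ClineDataset(
            locus=locus,
            samples=tuple(samples),
            meta={"dialect": "frequency", "rounded_populations": rounded},
        )
    return datasets


def write_frequency_table(datasets, path, *, sep=None) -> None:
    """Write datasets (mapping locus -> ClineDataset) as a count-dialect table.

    All datasets must share the same populations in the same order.
    """
    sep = _sep_for(path, sep)
    loci = list(datasets.keys())
    first = datasets[loci[0]]
    cols = {
        "population": [s.population_id for s in first.samples],
        "distance_km": [s.x for s in first.samples],
    }
    for locus in loci:
        ds = datasets[locus]
        if [s.population_id for s in ds.samples] != cols["population"]:
            raise ValidationError("all loci must share the same population rows to write one table")
        cols[f"{locus}_n"] = [s.n for s in ds.samples]
        cols[f"{locus}_k"] = [s.k for s in ds.samples]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


# -- fit result JSON -----------------------------------------------------


def _dataset_to_dict(data: ClineDataset) -> dict:
    return {
        "locus": data.locus,
        "samples": [
            {"population": s.population_id, "x": s.x, "n": s.n, "k": s.k} for s in data.samples
        ],
        "meta": data.meta,
    }


def _dataset_from_dict(d) -> ClineDataset:
    return ClineDataset(
        locus=d["locus"],
        samples=tuple(
            PopulationSample(s["population"], float(s["x"]), int(s["n"]), int(s["k"]))
            for s in d["samples"]
        ),
        meta=d.get("meta", {}),
    )


def write_fit_json(fit: ClineFitResult, data: ClineDataset, path, *, extra=None) -> None:
    """Serialize a fit (with its dataset and full provenance) to JSON."""
    payload = {
        "clinekit_version": __version__,
        "locus": data.locus,
        "params_hat": fit.params_hat.as_dict(),
        "lnL": fit.lnL,
        "spec": fit.spec.to_dict(),
        "support": {
            name: {
                "low": si.low,
                "high": si.high,
                "low_bounded": si.low_bounded,
                "high_bounded": si.high_bounded,
            }
            for name, si in fit.support.items()
        },
        "n_starts": fit.n_starts,
        "seed": fit.seed,
        "converged": fit.converged,
        "warnings": list(fit.warnings),
        "dataset": _dataset_to_dict(data),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit_json(path):
    """Load a fit JSON; returns (ClineFitResult, ClineDataset)."""
    with open(path) as fh:
        d = json.load(fh)
    fit = ClineFitResult(
        params_hat=ClineParams.from_dict(d["params_hat"]),
        lnL=float(d["lnL"]),
        spec=ModelSpec.from_dict(d["spec"]),
        support={
            name: SupportInterval(
                low=float(si["low"]),
                high=float(si["high"]),
                low_bounded=bool(si["low_bounded"]),
                high_bounded=bool(si["high_bounded"]),
            )
            for name, si in d.get("support", {}).items()
        },
        n_starts=int(d.get("n_starts", 0)),
        converged=bool(d.get("converged", False)),
        seed=d.get("seed"),
        warnings=tuple(d.get("warnings", ())),
    )
    return fit, _dataset_from_dict(d["dataset"])


# -- geography inputs ----------------------------------------------------


def read_coastline(path):
    """Coastline polyline from a 2-column TSV (lat, lon; optional header)
    or a GeoJSON LineString (coordinates are [lon, lat])."""
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        with open(path) as fh:
            gj = json.load(fh)
        geom = gj.get("geometry", gj)
        if geom.get("type") != "LineString":
            raise ValidationError("GeoJSON coastline must be a LineString")
        return [
            Locality(id=f"v{i}", latitude=float(lat), longitude=float(lon))
            for i, (lon, lat) in enumerate(geom["coordinates"])
        ]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if isinstance(df.iloc[0, 0], str):  # header row
        df = df.iloc[1:].reset_index(drop=True)
    return [
        Locality(id=f"v{i}", latitude=float(row[0]), longitude=float(row[1]))
        for i, row in df.iterrows()
    ]


def read_localities(path):
    """Sampling localities from a TSV with columns id, lat, lon."""
    df = pd.read_csv(path, sep="\t")
    missing = {"id", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValidationError(f"localities table is missing columns: {sorted(missing)}")
    return [
        Locality(id=str(r["id"]), latitude=float(r["lat"]), longitude=float(r["lon"]))
        for _, r in df.iterrows()
    ]


# -- optional VCF ingestion ----------------------------------------------


def read_vcf_panel(vcf_path, sample_map_path, *, r_allele: str = "ref"):
    """Build a GenotypePanel from a VCF of biallelic SNPs plus a sample map.

    The sample map is a TSV with columns id, population, group.  The
    R-allele dosage is counted against REF (default) or ALT per the
    ``r_allele`` flag.  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # deferred: VCF support is optional

    from .popgen import GenotypePanel

    if r_allele not in ("ref", "alt"):
        raise ValidationError("r_allele must be 'ref' or 'alt'")
    sample_map = pd.read_csv(sample_map_path, sep="\t", dtype=str)
    missing = {"id", "population", "group"} - set(sample_map.columns)
    if missing:
        raise ValidationError(f"sample map is missing columns: {sorted(missing)}")
    sample_map = sample_map.set_index("id")

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sample_map.index]
    if unknown:
        raise ValidationError(f"VCF samples missing from the sample map: {unknown}")

    data = {}
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            continue  # biallelic SNPs only
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        alt_dosage = {0: 0.0, 1: 1.0, 2: float("nan"), 3: 2.0}
        dosages = [alt_dosage[int(g)] for g in variant.gt_types]
        if r_allele == "ref":
            dosages = [2.0 - d if d == d else d for d in dosages]
        data[name] = dosages
    df = pd.DataFrame(data, index=samples)
    df.insert(0, "group", sample_map.loc[samples, "group"].to_numpy())
    df.insert(0, "population", sample_map.loc[samples, "population"].to_numpy())
    df.index.name = "id"
    return GenotypePanel(df)
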