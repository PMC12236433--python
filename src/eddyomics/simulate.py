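"""Synthetic two-eddy datasets with known ground truth.

Emulates the sampling design of a paired cyclone/anticyclone study: in each
eddy a high-resolution depth survey of 15 samples at 5 m intervals centred
on that eddy's deep chlorophyll maximum (DCM; shoaled ~20 m in the cyclone),
plus 18 diel DCM samples at ~4 h spacing.  On that design it generates

* ecotype marker abundances (reads per billion, RPB) as Gaussian-in-depth
  peaks with multiplicative lognormal noise — the high-light HLI ecotype
  peaks above the cyclone DCM and stays rare in the anticyclone;
* KO-aggregated gene abundances linearly coupled (slope beta) to a chosen
  ecotype's marker, plus depth-independent null KOs;
* diel metatranscriptomes: negative-binomial transcript counts whose means
  carry taxon-level anticyclone/cyclone fold changes and within-taxon
  differential expression, scaled by each sample's filtered volume and a
  per-sample capture efficiency;
* ERCC-style spike-in counts proportional to the known molecules added,
  with optional Poisson noise.

Everything is driven by one integer seed with per-stage derived substreams,
and every planted signal is recorded in a :class:`GroundTruth` object so
downstream stages can be scored by label recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "EcotypePeak",
    "EcotypeProfileModel",
    "GroundTruth",
    "SimulatedDataset",
    "default_ecotype_model",
    "load_ercc_reference",
    "stage_rng",
    "simulate_design",
    "simulate_ecotype_rpb",
    "simulate_ko_table",
    "simulate_transcriptomes",
    "simulate_dataset",
]

DCM_DEPTHS = {"cyclone": 100.0, "anticyclone": 120.0}  # ~20 m displacement
N_DEPTHS = 15
DEPTH_SPACING_M = 5.0
N_DIEL = 18
DIEL_SPACING_H = 4.0
VOLUME_RANGE_ML = (1000.0, 2000.0)
EFFICIENCY_RANGE = (0.2, 0.8)  # spike-in capture efficiency, counts per molecule
NB_DISPERSION = 0.1


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for a named stage of one global seed."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Design


def simulate_design(
    seed: int,
    dcm_depths: dict[str, float] | None = None,
    n_depths: int = N_DEPTHS,
    depth_spacing_m: float = DEPTH_SPACING_M,
    n_diel: int = N_DIEL,
    diel_spacing_h: float = DIEL_SPACING_H,
) -> SampleMetadata:
    """Two-eddy sampling design: depth survey plus diel DCM series.

    Per eddy, ``n_depths`` samples at ``depth_spacing_m`` intervals centred
    on that eddy's DCM, and ``n_diel`` DCM samples at ``diel_spacing_h``
    spacing.  Filtered volumes are drawn uniform in 1000-2000 ml.
    """
    rng = stage_rng(seed, "design")
    dcm_depths = dict(DCM_DEPTHS if dcm_depths is None else dcm_depths)
    rows = []
    half = (n_depths - 1) // 2
    for eddy, dcm in dcm_depths.items():
        tag = eddy[:3].upper()
        offsets = (np.arange(n_depths) - half) * depth_spacing_m
        for off in offsets:
            depth = dcm + off
            rows.append(
                dict(
                    sample_id=f"{tag}_D{depth:05.1f}",
                    eddy=eddy,
                    depth_m=depth,
                    dcm_depth_m=dcm,
                    volume_ml=rng.uniform(*VOLUME_RANGE_ML),
                    timepoint_h=np.nan,
                    station=f"{eddy}-center",
                )
            )
        for i in range(n_diel):
            rows.append(
                dict(
                    sample_id=f"{tag}_T{i * diel_spacing_h:04.0f}",
                    eddy=eddy,
                    depth_m=dcm,
                    dcm_depth_m=dcm,
                    volume_ml=rng.uniform(*VOLUME_RANGE_ML),
                    timepoint_h=i * diel_spacing_h,
                    station=f"{eddy}-center",
                )
            )
    return SampleMetadata(pd.DataFrame(rows))


def depth_survey_ids(meta: SampleMetadata) -> list[str]:
    """Samples belonging to the depth survey (no diel timepoint)."""
    f = meta.frame
    return [s for s in meta.sample_ids if not np.isfinite(f.at[s, "timepoint_h"])]


def diel_ids(meta: SampleMetadata) -> list[str]:
    f = meta.frame
    return [s for s in meta.sample_ids if np.isfinite(f.at[s, "timepoint_h"])]


# ---------------------------------------------------------------------------
# Ecotype depth profiles


@dataclass(frozen=True)
class EcotypePeak:
    """Gaussian-in-depth abundance peak of one ecotype.

    ``offset_m`` places the peak relative to the eddy's DCM (negative =
    shallower); ``height_rpb`` gives eddy-specific peak heights.
    """

    offset_m: float
    width_m: float
    height_rpb: dict[str, float]

    def __post_init__(self) -> None:
        if self.width_m <= 0 or any(h <= 0 for h in self.height_rpb.values()):
            raise ValueError("peak widths and heights must be strictly positive")


@dataclass(frozen=True)
class EcotypeProfileModel:
    dcm_depth_m: dict[str, float]
    peaks: dict[str, EcotypePeak]


def default_ecotype_model() -> EcotypeProfileModel:
    """Three-ecotype default: HLI shoaled and cyclone-enriched, HLII
    DCM-centred and anticyclone-dominant, LLI deep and eddy-neutral."""
    return EcotypeProfileModel(
        dcm_depth_m=dict(DCM_DEPTHS),
        peaks={
            "HLI": EcotypePeak(-10.0, 15.0, {"cyclone": 3000.0, "anticyclone": 300.0}),
            "HLII": EcotypePeak(0.0, 20.0, {"cyclone": 1500.0, "anticyclone": 4000.0}),
            "LLI": EcotypePeak(20.0, 15.0, {"cyclone": 800.0, "anticyclone": 800.0}),
        },
    )


def simulate_ecotype_rpb(
    model: EcotypeProfileModel,
    meta: SampleMetadata,
    seed: int,
    sigma: float = 0.2,
) -> AbundanceTable:
    """Ecotype marker RPB over depth-resolved samples.

    value(ecotype, sample) = height * exp(-(depth - (dcm + offset))^2 /
    (2 width^2)) * LogNormal(0, sigma).  Every sample must carry a depth.
    """
    rng = stage_rng(seed, "ecotype")
    f = meta.frame
    for s in meta.sample_ids:
        if not np.isfinite(f.at[s, "depth_m"]):
            raise ValidationError(f"sample {s!r} lacks a depth; cannot place it on a profile")
    ecotypes = list(model.peaks)
    values = np.empty((len(ecotypes), len(meta.sample_ids)))
    for i, eco in enumerate(ecotypes):
        peak = model.peaks[eco]
        for j, s in enumerate(meta.sample_ids):
            eddy = f.at[s, "eddy"]
            dcm = model.dcm_depth_m.get(eddy, f.at[s, "dcm_depth_m"])
            centre = dcm + peak.offset_m
            depth = f.at[s, "depth_m"]
            mean = peak.height_rpb.get(eddy, min(peak.height_rpb.values()))
            val = mean * np.exp(-((depth - centre) ** 2) / (2.0 * peak.width_m**2))
            noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            values[i, j] = val * noise
    ann = pd.DataFrame({"ecotype": ecotypes}, index=ecotypes)
    return AbundanceTable(
        pd.DataFrame(values, index=ecotypes, columns=meta.sample_ids), "its_rpb", ann
    )


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Planted signals of one simulated dataset.

    ``enriched_kos`` maps KO id -> (target ecotype, coupling slope beta);
    ``taxon_fc`` maps taxon -> true anticyclone/cyclone fold change;
    ``de_transcripts`` maps transcript -> true within-taxon log2 fold
    change (anticyclone over cyclone); ``spike_efficiency`` maps sample ->
    counts per molecule.
    """

    enriched_kos: dict[str, tuple[str, float]] = field(default_factory=dict)
    taxon_fc: dict[str, float] = field(default_factory=dict)
    de_transcripts: dict[str, float] = field(default_factory=dict)
    spike_efficiency: dict[str, float] = field(default_factory=dict)


def default_ground_truth(seed: int, n_enriched_kos: int = 10, target_ecotype: str = "HLI") -> GroundTruth:
    rng = stage_rng(seed, "truth")
    truth = GroundTruth()
    for i in range(n_enriched_kos):
        beta = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        truth.enriched_kos[f"K{10001 + i:05d}"] = (target_ecotype, beta)
    return truth


# ---------------------------------------------------------------------------
# KO tables coupled to ecotype markers


def simulate_ko_table(
    ecotype_table: AbundanceTable,
    truth: GroundTruth,
    n_null_kos: int = 200,
    seed: int = 0,
    sigma: float = 0.5,
) -> AbundanceTable:
    """KO-aggregated RPB: enriched KOs proportional to an ecotype marker,
    null KOs flat in depth; both with multiplicative lognormal noise.

    Enriched KO value = beta * ecotype RPB * LogNormal(0, sigma); null KO
    value = baseline * LogNormal(0, sigma) with a per-KO baseline drawn
    log-uniform in [10, 1000] RPB.
    """
    rng = stage_rng(seed, "ko")
    n_samples = len(ecotype_table.samples)
    kos, rows = [], []
    for ko, (ecotype, beta) in truth.enriched_kos.items():
        if beta <= 0:
            raise ValueError(f"coupling slope beta must be > 0 (KO {ko})")
        if ecotype not in ecotype_table.features:
            raise ValidationError(f"coupled ecotype {ecotype!r} missing from ecotype table")
        base = beta * ecotype_table.row(ecotype).to_numpy()
        noise = np.exp(rng.normal(0.0, sigma, n_samples)) if sigma > 0 else 1.0
        kos.append(ko)
        rows.append(base * noise)
    for i in range(n_null_kos):
        baseline = np.exp(rng.uniform(np.log(10.0), np.log(1000.0)))
        noise = np.exp(rng.normal(0.0, sigma, n_samples)) if sigma > 0 else 1.0
        kos.append(f"K{90001 + i:05d}")
        rows.append(np.full(n_samples, baseline) * noise)
    return AbundanceTable(
        pd.DataFrame(np.array(rows), index=kos, columns=ecotype_table.samples), "ko_rpb"
    )


# ---------------------------------------------------------------------------
# ERCC reference


def load_ercc_reference() -> pd.Series:
    """Packaged synthetic spike-in reference: 92 standards whose molar
    amounts are log-spaced over six orders of magnitude (fixture data for
    self-contained testing, not measured mix concentrations)."""
    with resources.files("eddyomics.data").joinpath("ercc_reference_synthetic.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("ercc_id")["molecules_per_sample"]


# ---------------------------------------------------------------------------
# Diel metatranscriptomes with spike-ins


COG_LETTERS = list("CDEFGHIJKLMNOPTUV")
PATHWAY_POOL = [f"map{100 + 10 * i:05d}" for i in range(24)]


def simulate_transcriptomes(
    meta: SampleMetadata,
    truth: GroundTruth,
    ercc_reference: pd.Series,
    seed: int = 0,
    n_fc_taxa: int = 12,
    fc_values: tuple[float, float] = (4.0, 0.25),
    n_null_taxa: int = 100,
    transcripts_per_taxon: int = 6,
    n_de: int = 5,
    de_log2fc: float = 3.0,
    n_null_transcripts_focal: int = 200,
    dispersion: float = NB_DISPERSION,
    poisson_noise: bool = True,
) -> tuple[AbundanceTable, AbundanceTable]:
    """Diel DCM metatranscriptomes for both eddies, with spike-in counts.

    Transcript counts are negative binomial with mean = (per-ml abundance)
    x (filtered volume) x (per-sample capture efficiency): the efficiency
    (uniform 0.2-0.8 counts per molecule) and volume are exactly what the
    spike-in calibration must undo.  Taxon-level anticyclone/cyclone fold
    changes and within-taxon differential expression (on a focal
    cyclone-enriched taxon) are planted per ``truth`` and recorded there.
    Spike counts are Poisson(efficiency x molecules), or the rounded
    noise-free product when ``poisson_noise`` is off.

    Returns ``(transcript_counts, spike_counts)``; the transcript table
    carries taxon/ecotype/KO/eggNOG/COG/pathway annotations.
    """
    rng = stage_rng(seed, "transcriptome")
    samples = meta.sample_ids
    f = meta.frame
    if not truth.spike_efficiency:
        for s in samples:
            truth.spike_efficiency[s] = float(rng.uniform(*EFFICIENCY_RANGE))
    missing = [s for s in samples if s not in truth.spike_efficiency]
    if missing:
        raise ValidationError(f"no spike efficiency for samples {missing[:3]}")

    # taxon roster: planted fold changes, then nulls; first FC<1 taxon is focal
    if not truth.taxon_fc:
        half = n_fc_taxa // 2
        for i in range(n_fc_taxa):
            fc = fc_values[0] if i < half else fc_values[1]
            truth.taxon_fc[f"Prochlorococcus_A_sp{i + 1:03d}"] = fc
        for i in range(n_null_taxa):
            truth.taxon_fc[f"Prochlorococcus_A_null{i + 1:03d}"] = 1.0
    focal = next((t for t, fc in truth.taxon_fc.items() if fc < 1.0), None)

    transcript_ids: list[str] = []
    taxon_of: list[str] = []
    perml_base: list[float] = []
    l2fc_of: list[float] = []
    for taxon, fc in truth.taxon_fc.items():
        n_t = transcripts_per_taxon
        if taxon == focal:
            n_t = n_de + n_null_transcripts_focal
        for k in range(n_t):
            tid = f"{taxon}|tr{k + 1:04d}"
            transcript_ids.append(tid)
            taxon_of.append(taxon)
            perml_base.append(float(np.exp(rng.uniform(np.log(0.02), np.log(0.2)))))
            if taxon == focal and k < n_de:
                l2 = de_log2fc if k % 2 == 0 else -de_log2fc
                truth.de_transcripts[tid] = l2
                l2fc_of.append(l2)
            else:
                l2fc_of.append(0.0)

    n_tr = len(transcript_ids)
    counts = np.empty((n_tr, len(samples)))
    fc_arr = np.array([truth.taxon_fc[t] for t in taxon_of])
    base_arr = np.array(perml_base)
    shift_arr = 2.0 ** np.array(l2fc_of)
    for j, s in enumerate(samples):
        anti = f.at[s, "eddy"] == "anticyclone"
        mult = fc_arr * shift_arr if anti else np.ones(n_tr)
        mean = base_arr * mult * meta.volume_ml(s) * truth.spike_efficiency[s]
        if dispersion > 0:
            # NB via gamma-Poisson mixture: shape 1/alpha, scale mean*alpha
            lam = rng.gamma(1.0 / dispersion, mean * dispersion)
            counts[:, j] = rng.poisson(lam)
        else:
            counts[:, j] = rng.poisson(mean) if poisson_noise else np.round(mean)

    ann = _annotate_transcripts(transcript_ids, taxon_of, truth, seed)
    transcript_table = AbundanceTable(
        pd.DataFrame(counts, index=transcript_ids, columns=samples), "transcript_count", ann
    )

    mols = ercc_reference.to_numpy(dtype=float)
    spikes = np.empty((mols.size, len(samples)))
    for j, s in enumerate(samples):
        lam = truth.spike_efficiency[s] * mols
        spikes[:, j] = rng.poisson(lam) if poisson_noise else np.round(lam)
    spike_table = AbundanceTable(
        pd.DataFrame(spikes, index=list(ercc_reference.index), columns=samples),
        "transcript_count",
    )
    return transcript_table, spike_table


def _annotate_transcripts(
    transcript_ids: list[str], taxon_of: list[str], truth: GroundTruth, seed: int
) -> pd.DataFrame:
    """Taxon, ecotype, and functional annotations for simulated transcripts.

    Cyclone-enriched taxa (true FC < 1) are labelled HLI, anticyclone-
    enriched HLII, nulls alternate; each transcript gets a unique eggNOG
    id, one COG letter and 1-2 pathways from a fixed pool.
    """
    rng = stage_rng(seed, "annotations")
    rows = []
    for i, (tid, taxon) in enumerate(zip(transcript_ids, taxon_of)):
        fc = truth.taxon_fc[taxon]
        ecotype = "HLI" if fc < 1.0 else ("HLII" if fc > 1.0 else ("HLI", "HLII")[i % 2])
        pathways = sorted(rng.choice(PATHWAY_POOL, size=rng.integers(1, 3), replace=False))
        rows.append(
            dict(
                taxon=taxon,
                ecotype=ecotype,
                ko=f"K{rng.integers(1, 20000):05d}",
                eggnog=f"ENOG50{i:04d}",
                cog_categories=str(rng.choice(COG_LETTERS)),
                pathways=",".join(pathways),
            )
        )
    return pd.DataFrame(rows, index=transcript_ids)


# ---------------------------------------------------------------------------
# One-call dataset


@dataclass
class SimulatedDataset:
    meta: SampleMetadata
    ecotype_rpb: AbundanceTable      # depth-survey samples only
    ko_rpb: AbundanceTable           # depth-survey samples only
    transcript_counts: AbundanceTable  # diel samples only
    spike_counts: AbundanceTable
    ercc_reference: pd.Series
    truth: GroundTruth


def simulate_dataset(
    seed: int,
    ecotype_sigma: float = 0.2,
    ko_sigma: float = 0.5,
    n_enriched_kos: int = 10,
    n_null_kos: int = 200,
    **transcriptome_kwargs,
) -> SimulatedDataset:
    """Generate the full two-eddy dataset under the default study design."""
    meta = simulate_design(seed)
    depth_meta = meta.subset(depth_survey_ids(meta))
    diel_meta = meta.subset(diel_ids(meta))
    model = default_ecotype_model()
    ecotype = simulate_ecotype_rpb(model, depth_meta, seed, sigma=ecotype_sigma)
    truth = default_ground_truth(seed, n_enriched_kos=n_enriched_kos)
    ko = simulate_ko_table(ecotype, truth, n_null_kos=n_null_kos, seed=seed, sigma=ko_sigma)
    reference = load_ercc_reference()
    transcripts, spikes = simulate_transcriptomes(
        diel_meta, truth, reference, seed=seed, **transcriptome_kwargs
    )
    return SimulatedDataset(meta, ecotype, ko, transcripts, spikes, reference, truth)
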