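"""End-to-end pipeline runs on synthetic data, with ground-truth scoring.

Convenience layer tying the stages together in study order: simulate a
two-eddy dataset, calibrate spike-ins, normalize to per-ml, test the HLI
depth-profile enrichment, screen KOs, flag taxa, and test within-taxon
expression — then score every stage against the generator's planted truth.
Also provides all-null generators for empirical type-I error checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ercc import ErccCalibrationModel
from .expression import ExpressionDifferentialModel
from .profiles import ProfileEnrichmentModel, to_relative_abundance
from .simulate import (
    GroundTruth,
    SimulatedDataset,
    depth_survey_ids,
    diel_ids,
    load_ercc_reference,
    simulate_dataset,
    simulate_design,
    simulate_transcriptomes,
    stage_rng,
)
from .stats import kruskal_wallis_table, nb_wald_matrix
from .taxa import TaxonDifferentialModel, sum_by_taxon
from .traits import TraitEnrichmentModel

__all__ = ["RecoveryScores", "run_and_score", "null_rejection_rates"]


@dataclass
class RecoveryScores:
    """Ground-truth recovery metrics of one pipeline run."""

    ercc_max_rel_error: float
    profile_p_value: float
    profile_direction: int
    ko_recovered: int
    ko_planted: int
    ko_false_passes: int
    n_null_kos: int
    taxa_correct: int
    taxa_planted: int
    taxa_false_flags: int
    n_null_taxa: int
    de_sides_recovered: int
    de_planted: int
    de_false_sides: int
    n_de_tested: int


def run_and_score(seed: int, dataset: SimulatedDataset | None = None) -> RecoveryScores:
    """Run every stage on one synthetic dataset and score label recovery."""
    ds = dataset if dataset is not None else simulate_dataset(seed)
    diel = ds.meta.subset(diel_ids(ds.meta))
    depth = ds.meta.subset(ds.ecotype_rpb.samples)

    cal = ErccCalibrationModel(ds.spike_counts, ds.ercc_reference).fit()
    eff = pd.Series(ds.truth.spike_efficiency)
    fitted = cal.frame["correction_factor"]
    ercc_err = float(((fitted - eff).abs() / eff).max())
    per_ml = cal.normalize(ds.transcript_counts, diel)

    profile = ProfileEnrichmentModel(ds.ecotype_rpb, depth, "HLI").fit()

    traits = TraitEnrichmentModel(ds.ko_rpb, ds.ecotype_rpb, depth).fit()
    truth_kos = set(ds.truth.enriched_kos)
    passing = {r.ko_id for r in traits.passing}

    species = sum_by_taxon(per_ml, per_ml.annotations["taxon"])
    taxa = TaxonDifferentialModel(species, diel).fit()
    truth_anti = {t for t, fc in ds.truth.taxon_fc.items() if fc > 1}
    truth_cyc = {t for t, fc in ds.truth.taxon_fc.items() if fc < 1}
    flagged_anti = {r.taxon_id for r in taxa.flagged("anticyclone_enriched")}
    flagged_cyc = {r.taxon_id for r in taxa.flagged("cyclone_enriched")}

    expr = ExpressionDifferentialModel(per_ml, diel, taxa=sorted(flagged_cyc)).fit()
    rec = {r.transcript_id: r for r in expr.records}
    de_hits = sum(
        1
        for t, l2 in ds.truth.de_transcripts.items()
        if t in rec and rec[t].side == ("anticyclone" if l2 > 0 else "cyclone")
    )
    de_false = sum(
        1 for r in expr.records if r.side != "none" and r.transcript_id not in ds.truth.de_transcripts
    )

    return RecoveryScores(
        ercc_max_rel_error=ercc_err,
        profile_p_value=profile.p_value,
        profile_direction=profile.direction,
        ko_recovered=len(passing & truth_kos),
        ko_planted=len(truth_kos),
        ko_false_passes=len(passing - truth_kos),
        n_null_kos=len(ds.ko_rpb.features) - len(truth_kos),
        taxa_correct=len(flagged_anti & truth_anti) + len(flagged_cyc & truth_cyc),
        taxa_planted=len(truth_anti) + len(truth_cyc),
        taxa_false_flags=len((flagged_anti | flagged_cyc) - truth_anti - truth_cyc),
        n_null_taxa=len([t for t, fc in ds.truth.taxon_fc.items() if fc == 1]),
        de_sides_recovered=de_hits,
        de_planted=len(ds.truth.de_transcripts),
        de_false_sides=de_false,
        n_de_tested=len(expr.records),
    )


def null_rejection_rates(seed: int, n_features: int = 1000) -> dict[str, float]:
    """Empirical alpha = 0.05 rejection rates of the three test stages on
    all-null synthetic data (raw p-values, >= n_features features each).

    * profile: flat lognormal depth profiles, no eddy effect, rank test on
      relative abundances over the 8 at-or-above-DCM samples per eddy;
    * taxon: per-ml taxon sums with every true fold change 1, rank test
      over the 18 + 18 diel samples;
    * expression: within-taxon fractions of null transcripts, NB Wald test.
    """
    rng = stage_rng(seed, "null-bench")
    meta = simulate_design(seed)
    depth = meta.subset(depth_survey_ids(meta))
    diel = meta.subset(diel_ids(meta))

    # -- profile stage: flat profiles, multiplicative noise only
    window = [
        s
        for s in depth.sample_ids
        if depth.frame.at[s, "depth_m"] <= depth.frame.at[s, "dcm_depth_m"]
    ]
    vals = np.exp(rng.normal(0.0, 0.2, size=(n_features, len(window))))
    rel = vals / vals.sum(axis=0)
    labels = [depth.frame.at[s, "eddy"] for s in window]
    idx_c = [i for i, e in enumerate(labels) if e == "cyclone"]
    idx_a = [i for i, e in enumerate(labels) if e == "anticyclone"]
    _, p = kruskal_wallis_table(rel, idx_c, idx_a)
    profile_rate = float((p < 0.05).mean())

    # -- taxon stage: all-null transcriptome through the real normalization
    truth = GroundTruth(taxon_fc={f"null{i:04d}": 1.0 for i in range(n_features)})
    counts, spikes = simulate_transcriptomes(
        diel, truth, load_ercc_reference(), seed=seed, transcripts_per_taxon=2
    )
    cal = ErccCalibrationModel(spikes, load_ercc_reference()).fit()
    per_ml = cal.normalize(counts, diel)
    species = sum_by_taxon(per_ml, per_ml.annotations["taxon"])
    cols = list(species.values.columns)
    idx_c = [cols.index(s) for s in diel.samples_in_eddy("cyclone")]
    idx_a = [cols.index(s) for s in diel.samples_in_eddy("anticyclone")]
    _, p = kruskal_wallis_table(species.values.to_numpy(), idx_c, idx_a)
    taxon_rate = float((p < 0.05).mean())

    # -- expression stage: one large null taxon, fraction pseudo-counts
    truth2 = GroundTruth(taxon_fc={"nullT": 1.0})
    counts2, spikes2 = simulate_transcriptomes(
        diel, truth2, load_ercc_reference(), seed=seed + 1,
        transcripts_per_taxon=n_features,
    )
    cal2 = ErccCalibrationModel(spikes2, load_ercc_reference()).fit()
    per_ml2 = cal2.normalize(counts2, diel)
    from .expression import within_taxon_normalize

    fractions, _ = within_taxon_normalize(per_ml2, per_ml2.annotations["taxon"])
    pseudo = np.rint(fractions.values.to_numpy() * 1e6)
    cols2 = list(fractions.values.columns)
    idx_c2 = [cols2.index(s) for s in diel.samples_in_eddy("cyclone")]
    idx_a2 = [cols2.index(s) for s in diel.samples_in_eddy("anticyclone")]
    _, _, p = nb_wald_matrix(pseudo[:, idx_c2], pseudo[:, idx_a2])
    expression_rate = float((p < 0.05).mean())

    return {
        "profile": profile_rate,
        "taxon": taxon_rate,
        "expression": expression_rate,
    }
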