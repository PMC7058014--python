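"""Quantitative classifiers for simulated HAM mRNA expression patterns.

Wild-type SAMs show an apical(low)-basal(high) gradient of HAM mRNA:
little in the epidermis, where miR171 is produced, and plenty in the
corpus.  Ectopic ATML1 activation switches miR171 production on in the
inner layers and collapses HAM mRNA everywhere.  The experimental
readout of both statements is qualitative, so this module fixes explicit,
configurable thresholds and records them with every verdict.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .model import SimulationResult, layer_means
from .template import CORPUS, L1, L2, CellTemplate


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class GradientCriteria:
    """Thresholds operationalising the apical(low)-basal(high) HAM mRNA gradient.

    ``l1_ratio_max``: largest allowed ratio of L1 mean to corpus mean
    HAM mRNA (default 0.2, i.e. at least five-fold epidermal depletion).
    ``require_monotone``: demand L1 mean < L2 mean < corpus mean.
    ``corpus_floor``: minimum corpus mean HAM mRNA in a.u., rejecting
    globally suppressed states.  ``gfp_l1_only``: require the (immobile)
    GFP reporter protein to stay epidermal — corpus mean below 5 % of
    the L1 mean.
    """

    l1_ratio_max: float = 0.2
    require_monotone: bool = True
    corpus_floor: float = 0.1
    gfp_l1_only: bool = True
    gfp_corpus_frac: float = 0.05

    def __post_init__(self):
        if not 0 < self.l1_ratio_max < 1:
            raise ClassificationError("l1_ratio_max must lie in (0, 1)")
        if self.corpus_floor <= 0:
            raise ClassificationError("corpus_floor must be positive")
        if not 0 < self.gfp_corpus_frac < 1:
            raise ClassificationError("gfp_corpus_frac must lie in (0, 1)")


@dataclass(frozen=True)
class PatternVerdict:
    passed: bool
    metrics: dict
    criteria_used: dict


def classify_wt_gradient(
    result: SimulationResult,
    template: CellTemplate,
    criteria: GradientCriteria | None = None,
) -> PatternVerdict:
    """Judge whether a steady state shows the wild-type HAM mRNA gradient.

    Refuses unconverged results: a transient cannot be classified as a
    pattern.  The verdict is a pure function of the computed layer
    means and the criteria, both of which are reported in full.
    """
    criteria = criteria or GradientCriteria()
    if not result.converged:
        raise ClassificationError("refusing to classify an unconverged simulation")
    hamr = layer_means(result.final_state, template, "ham_mrna")
    ratio = hamr[L1] / hamr[CORPUS] if hamr[CORPUS] > 0 else float("inf")
    monotone = hamr[L1] < hamr[L2] < hamr[CORPUS]

    checks = {
        "l1_ratio_ok": ratio < criteria.l1_ratio_max,
        "corpus_floor_ok": hamr[CORPUS] > criteria.corpus_floor,
    }
    if criteria.require_monotone:
        checks["monotone_ok"] = monotone
    metrics = {
        "ham_mrna_layer_means": hamr,
        "l1_corpus_ratio": ratio,
        "monotone": monotone,
    }
    if criteria.gfp_l1_only:
        gfpp = layer_means(result.final_state, template, "gfp_protein")
        gfp_ratio = (
            gfpp[CORPUS] / gfpp[L1] if gfpp[L1] > 0 else (0.0 if gfpp[CORPUS] == 0 else float("inf"))
        )
        checks["gfp_l1_only_ok"] = gfp_ratio < criteria.gfp_corpus_frac
        metrics["gfp_protein_layer_means"] = gfpp
        metrics["gfp_corpus_l1_ratio"] = gfp_ratio
    metrics["checks"] = checks
    return PatternVerdict(
        passed=all(checks.values()),
        metrics=metrics,
        criteria_used=asdict(criteria),
    )


def classify_suppression(
    perturbed: SimulationResult,
    wildtype: SimulationResult,
    template: CellTemplate,
    reduction_threshold: float = 0.5,
) -> PatternVerdict:
    """Judge whether a perturbed input suppresses HAM mRNA in every layer.

    Passes iff the perturbed steady-state mean HAM mRNA is (i) strictly
    below the matched wild-type mean in every layer and (ii) below
    ``reduction_threshold`` times the wild-type mean in the
    sub-epidermal layers (L2 and corpus), where wild-type expression is
    substantial.  The epidermis is held to strict reduction only: its
    wild-type level is already near zero, so a further fold-change
    requirement there would be vacuous noise, not "dramatic reduction".
    Both simulations must have converged on the same template with the
    same parameters — the input field is the only allowed difference.
    """
    if not (perturbed.converged and wildtype.converged):
        raise ClassificationError("both simulations must have converged")
    if not 0 < reduction_threshold <= 1:
        raise ClassificationError("reduction_threshold must lie in (0, 1]")
    for key in ("template_checksum", "params"):
        a = perturbed.provenance.get(key)
        b = wildtype.provenance.get(key)
        if a is not None and b is not None and a != b:
            raise ClassificationError(f"simulations differ in {key}; comparison is invalid")
    pert = layer_means(perturbed.final_state, template, "ham_mrna")
    wt = layer_means(wildtype.final_state, template, "ham_mrna")
    ratios = {
        layer: (pert[layer] / wt[layer] if wt[layer] > 0 else float("inf"))
        for layer in (L1, L2, CORPUS)
    }
    strictly_reduced = all(r < 1.0 for r in ratios.values())
    deep_collapsed = all(ratios[layer] < reduction_threshold for layer in (L2, CORPUS))
    passed = strictly_reduced and deep_collapsed
    return PatternVerdict(
        passed=passed,
        metrics={
            "ham_mrna_layer_means_perturbed": pert,
            "ham_mrna_layer_means_wildtype": wt,
            "layer_ratios": ratios,
        },
        criteria_used={"reduction_threshold": reduction_threshold},
    )
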