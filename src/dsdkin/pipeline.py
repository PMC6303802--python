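"""End-to-end analysis: enumerate, characterize, estimate, assemble, score.

This is the orchestration layer behind the command-line interface: given a
system file it runs domain-level enumeration and condensation, builds the
first-step model for every bimolecular macrostate pair with a condensed
reaction, simulates toy first-step trajectories, estimates rate constants
with Bayesian error bars, assembles the first-step CRN, and (when maximum
concentrations are provided) computes temporary and permanent depletion
scores.  Reports are deterministic given the seed.
"""

from __future__ import annotations

import json
import os
from typing import Mapping, Optional

import numpy as np

from .core import read_system_spec, write_structure
from .crn import (
    assemble_first_step_crn,
    compute_permanent_depletion,
    compute_temporary_depletion,
)
from .enumeration import (
    TimescalePolicy,
    build_reaction_subnetwork,
    condense_reactions,
    enumerate_detailed_reactions,
    find_resting_macrostates,
)
from .firststep import build_first_step_model, derive_stop_states
from .macrostates import (
    ApproximationPolicy,
    estimate_conformation_probabilities,
)
from .rates import (
    SPURIOUS,
    UNPRODUCTIVE,
    estimate_bimolecular_rates,
)
from .simulate import (
    ToyEnergyModel,
    ToyKineticModel,
    sample_boltzmann_structures,
    simulate_first_step_trajectories,
)

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "n_trajectories": 200,
    "p": 0.51,
    "p_prime": 0.51,
    "toehold_threshold": 7,
    "max_strands": 6,
    "max_complexes": 1000,
    "thermo_samples": 500,
    "max_ensemble": 20000,
    "run_thermo": True,
}


def _estimate_pair(A, network, kinetic, energy, n, rng):
    model = build_first_step_model(list(A), network.condensed_reactions)
    sub = build_reaction_subnetwork(list(A), network)
    stops = derive_stop_states(list(A), sub, model)
    records = simulate_first_step_trajectories(
        list(A), kinetic, stops, n=n, seed=rng, energy_model=energy
    )
    for r in model:
        if r.kind == "unproductive":
            r.estimate = estimate_bimolecular_rates(records, UNPRODUCTIVE)
        elif r.kind == "spurious":
            r.estimate = estimate_bimolecular_rates(records, SPURIOUS)
        else:
            r.estimate = estimate_bimolecular_rates(records, r.index)
    return model, records


def run_pipeline(
    spec_path_or_text,
    config: Optional[Mapping] = None,
    seed: int = 0,
    out_dir: Optional[str] = None,
) -> dict:
    """Run the full analysis and return (and optionally write) the report."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    rng = np.random.default_rng(seed)
    spec = read_system_spec(spec_path_or_text)
    policy = TimescalePolicy(toehold_threshold=int(cfg["toehold_threshold"]))
    approx = ApproximationPolicy(p=float(cfg["p"]), p_prime=float(cfg["p_prime"]))
    kinetic = ToyKineticModel()
    energy = ToyEnergyModel()

    network = enumerate_detailed_reactions(
        spec,
        policy=policy,
        max_strands=int(cfg["max_strands"]),
        max_complexes=int(cfg["max_complexes"]),
    )
    find_resting_macrostates(network)
    condensed = condense_reactions(network)

    report: dict = {
        "seed": seed,
        "network": network.to_json(),
        "macrostates": {
            m.name: [write_structure(c) for c in sorted(m.conformations, key=write_structure)]
            for m in network.resting_macrostates
        },
    }

    # conformation probabilities (requires sequences and small ensembles)
    sequenced = all(d.sequence is not None for d in spec.domains.values())
    if sequenced and cfg["run_thermo"]:
        thermo = {}
        for m in network.resting_macrostates:
            strands = next(iter(m.conformations)).strands
            try:
                sampler = lambda k, r, s=strands: sample_boltzmann_structures(  # noqa: E731
                    s, energy, k, seed=r, max_structures=int(cfg["max_ensemble"])
                )
                est = estimate_conformation_probabilities(
                    sampler,
                    m,
                    approx,
                    max_samples=int(cfg["thermo_samples"]),
                    seed=int(rng.integers(2**31 - 1)),
                )
                thermo[m.name] = {
                    "N": est.N,
                    "p_spurious": est.p_spurious,
                    "p_hat": est.p_hat,
                }
            except Exception as exc:  # oversized ensemble etc.
                thermo[m.name] = {"skipped": str(exc)}
        report["conformation_probabilities"] = thermo

    # first-step models for every bimolecular condensed reactant pair
    pairs = sorted(
        {r.reactants for r in condensed if len(r.reactants) == 2},
        key=lambda ms: tuple(m.name for m in ms),
    )
    all_reactions = []
    rates_report = {}
    for A in pairs:
        model, _records = _estimate_pair(
            A, network, kinetic, energy, int(cfg["n_trajectories"]), rng
        )
        all_reactions.extend(model)
        for r in model:
            est = r.estimate
            entry = {
                "kind": r.kind,
                "reactants": [m.name for m in r.reactants],
                "products": (
                    r.products
                    if isinstance(r.products, str)
                    else [m.name for m in r.products]
                ),
                "N": est.N,
                "N_i": est.N_i,
                "k1": est.k1_hat,
                "sigma_k1": est.sigma_k1,
                "k2": est.k2_hat,
                "sigma_k2": est.sigma_k2,
                "zero_success": est.zero_success,
                "k1_upper_bound": est.k1_upper_bound,
            }
            key = "+".join(m.name for m in r.reactants) + f"->{r.index}"
            rates_report[key] = entry
    report["rates"] = rates_report

    crn = assemble_first_step_crn(all_reactions)
    report["crn"] = {
        "species": crn.species,
        "reactions": [repr(r) for r in crn.reactions],
        "skipped": crn.skipped,
    }

    # depletion scores need maximum concentrations
    if spec.concentrations:
        conc = {name: c for name, c in spec.concentrations.items()}
        K: dict[tuple[str, str], float] = {}
        k1s: dict[tuple[str, str], float] = {}
        beta_is_bound = False
        for r in all_reactions:
            est = r.estimate
            a, b = (r.reactants[0].name, r.reactants[-1].name)
            if r.kind == "unproductive" and est and not est.zero_success and est.k2_hat:
                Kab = est.k1_hat / est.k2_hat
                K[(a, b)] = Kab
                K[(b, a)] = Kab
            if r.kind == "spurious" and est:
                k1 = est.k1_hat if not est.zero_success else (est.k1_upper_bound or 0.0)
                if est.zero_success:
                    beta_is_bound = True
                k1s[(a, b)] = k1s.get((a, b), 0.0) + k1
                if a != b:
                    k1s[(b, a)] = k1s.get((b, a), 0.0) + k1
        tmp = compute_temporary_depletion(K, conc)
        perm = compute_permanent_depletion(k1s, conc, upper_bound=beta_is_bound)
        report["depletion"] = {
            "alpha": tmp.alpha,
            "alpha_A": tmp.alpha_A,
            "alpha_AB": {f"{a}|{b}": v for (a, b), v in tmp.alpha_AB.items()},
            "beta": perm.beta,
            "beta_A": perm.beta_A,
            "beta_is_upper_bound": perm.flagged_upper_bound,
        }
    else:
        report["depletion"] = {
            "skipped": "no maximum concentrations provided; systems without "
            "concentration bounds should not be judged by depletion scores"
        }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
        with open(os.path.join(out_dir, "crn.txt"), "w") as fh:
            fh.write(crn.export_text())
    return report
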