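"""End-to-end orchestration: simulate -> repertoires -> rates -> networks ->
permutation inference -> GLMM, with a reproducibility manifest.

Stages are composable and run in dependency order; each writes plain-text
outputs (CSV/JSON) under the run directory and is recorded in a manifest
with content hashes, seeds and the package version, so a re-run with the
same config reproduces deterministic stages bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .glmm import GlmmSpec, fit_glmm
from .network import DyadMatrix, build_matrix, normalized_degree
from .permutation import mrqap_dsp, node_level_regression
from .rates import BEHAVIOURS, rate_matrix, rates_table, scan_independence_check
from .repertoire import (
    build_repertoires,
    classify_sequence,
    dyad_repertoire_summary,
)
from .scoring import score_dyad_attributes
from .sequences import group_sequences, sequences_by_id
from .synthetic import SyntheticConfig, generate_follows, generate_population
from .types import MODALITIES, ValidationError
from .network import unordered_dyads

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "repertoire",
    "rates",
    "networks",
    "mrqap",
    "nodereg",
    "glmm",
)


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    ``synthetic`` holds generator parameters (ignored when input CSVs are
    supplied via ``inputs``); ``n_perm_mrqap``/``n_perm_node`` control the
    permutation counts; ``stages`` selects which stages run.
    """

    out_dir: Path
    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES
    synthetic: Dict[str, object] = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)
    n_perm_mrqap: int = 2000
    n_perm_node: int = 10000
    mrqap_outcome: str = "proximity"
    mrqap_predictors: Tuple[str, ...] = (
        "kappa_visual",
        "kappa_tactile",
        "kappa_auditory_short",
        "kappa_auditory_long",
    )
    glmm_response: str = "homogeneous_present"
    glmm_effects: Tuple[str, ...] = ("same_sex", "same_age_class", "proximity_rate")

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    @staticmethod
    def from_yaml(path: str | Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("stages", "mrqap_predictors", "glmm_effects"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _jsonable(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the requested stages and return the manifest (also written
    to ``manifest.json`` in the run directory)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    manifest: Dict[str, object] = {
        "seed": config.seed,
        "stages": list(config.stages),
        "version": __import__("gestnet").__version__,
    }

    def _record(name: str, path: Path) -> None:
        outputs[name] = path.name

    syn_cfg = SyntheticConfig(seed=config.seed, **config.synthetic)

    # ---- inputs: simulate or load ------------------------------------
    if "simulate" in config.stages:
        individuals, kin_pairs, repertoires = generate_population(syn_cfg)
        scans, events = generate_follows(syn_cfg, individuals, repertoires)
        gio.write_individuals(individuals, out / "individuals.csv")
        gio.write_kin_pairs(kin_pairs, out / "kin_pairs.csv")
        gio.write_scans(scans, out / "scans.csv")
        gio.write_gestures(events, out / "gestures.csv")
        for name in ("individuals", "kin_pairs", "scans", "gestures"):
            _record(name, out / f"{name}.csv")
        manifest["synthetic_config"] = dataclasses.asdict(syn_cfg)
    else:
        required = ("individuals", "kin_pairs", "scans", "gestures")
        missing = [k for k in required if k not in config.inputs]
        if missing:
            raise ValidationError(
                f"stage inputs missing: {missing} (enable 'simulate' or "
                "provide them in config.inputs)"
            )
        individuals = gio.read_individuals(config.inputs["individuals"])
        kin_pairs = gio.read_kin_pairs(config.inputs["kin_pairs"])
        known = {ind.id for ind in individuals}
        scans = gio.read_scans(config.inputs["scans"], known_ids=known)
        events = gio.read_gestures(config.inputs["gestures"], known_ids=known)

    ids = sorted(ind.id for ind in individuals)
    by_id = {ind.id: ind for ind in individuals}
    adults = set(ids)
    events = group_sequences(events)

    # ---- repertoires and dyadic overlap ------------------------------
    if "repertoire" in config.stages:
        observed = build_repertoires(events, adults)
        rows = []
        for a, b in unordered_dyads(ids):
            for modality in (None, *MODALITIES):
                summ = dyad_repertoire_summary(observed[a], observed[b], modality)
                rows.append(
                    {
                        "id_a": a,
                        "id_b": b,
                        "modality": modality or "all",
                        "kappa": summ.kappa,
                        "homog_size": summ.homog_size,
                        "heterog_size": summ.heterog_size,
                    }
                )
        dyad_frame = pd.DataFrame(rows)
        dyad_frame.to_csv(out / "dyad_repertoire.csv", index=False)
        _record("dyad_repertoire", out / "dyad_repertoire.csv")

        seq_rows = []
        for seq_id, seq_events in sequences_by_id(events).items():
            cls = classify_sequence(seq_events, observed)
            if cls is None:
                continue
            seq_rows.append(
                {
                    "sequence_id": seq_id,
                    "signaller_id": cls.signaller_id,
                    "recipient_id": cls.recipient_id,
                    "homog_repertoire_size": cls.homog_repertoire_size,
                    "heterog_repertoire_size": cls.heterog_repertoire_size,
                }
            )
        pd.DataFrame(seq_rows).to_csv(out / "sequence_classes.csv", index=False)
        _record("sequence_classes", out / "sequence_classes.csv")
        manifest["n_sequences"] = len(seq_rows)
    else:
        observed = build_repertoires(events, adults)
        dyad_frame = None

    # ---- bonding rates ------------------------------------------------
    if "rates" in config.stages:
        table = rates_table(scans, ids)
        table.to_csv(out / "bonding_rates.csv", index=False)
        _record("bonding_rates", out / "bonding_rates.csv")
        checks = scan_independence_check(scans)
        pd.DataFrame([dataclasses.asdict(c) for c in checks]).to_csv(
            out / "scan_independence.csv", index=False
        )
        _record("scan_independence", out / "scan_independence.csv")

    # ---- network matrices and centrality ------------------------------
    networks: Dict[str, DyadMatrix] = {}
    if {"networks", "mrqap", "nodereg"} & set(config.stages):
        for behaviour in BEHAVIOURS:
            networks[behaviour] = rate_matrix(scans, ids, behaviour)
        for modality in (None, *MODALITIES):
            key = f"kappa_{modality}" if modality else "kappa_all"
            values = {}
            for a, b in unordered_dyads(ids):
                summ = dyad_repertoire_summary(observed[a], observed[b], modality)
                if not math.isnan(summ.kappa):
                    values[(a, b)] = summ.kappa
            networks[key] = build_matrix(values, directed=False, node_ids=ids)
    if "networks" in config.stages:
        cent_rows = []
        for name, matrix in networks.items():
            gio.write_matrix(matrix, out / f"net_{name}.csv")
            _record(f"net_{name}", out / f"net_{name}.csv")
            if matrix.directed:
                for mode in ("indegree", "outdegree"):
                    series = normalized_degree(matrix, mode)
                    for node, value in series.items():
                        cent_rows.append(
                            {"network": name, "node": node, "mode": mode,
                             "centrality": value}
                        )
            else:
                series = normalized_degree(matrix, "n_degree")
                for node, value in series.items():
                    cent_rows.append(
                        {"network": name, "node": node, "mode": "n_degree",
                         "centrality": value}
                    )
        pd.DataFrame(cent_rows).to_csv(out / "centrality.csv", index=False)
        _record("centrality", out / "centrality.csv")

    # ---- MRQAP -------------------------------------------------------
    if "mrqap" in config.stages:
        y = networks[config.mrqap_outcome]
        xs = {name: networks[name] for name in config.mrqap_predictors}
        result = mrqap_dsp(
            y, xs, n_perm=config.n_perm_mrqap, seed=config.seed
        )
        payload = result.to_dict()
        payload["outcome"] = config.mrqap_outcome
        (out / "mrqap.json").write_text(
            json.dumps(payload, indent=2, default=_jsonable), encoding="utf-8"
        )
        _record("mrqap", out / "mrqap.json")

    # ---- node-level regression ---------------------------------------
    if "nodereg" in config.stages:
        y = normalized_degree(networks[config.mrqap_outcome], "indegree")
        xs = pd.DataFrame(
            {
                f"{name}_ndeg": normalized_degree(networks[name], "n_degree")
                for name in config.mrqap_predictors
                if not networks[name].directed
            }
        )
        xs["sex_male"] = [1.0 if by_id[i].sex == "male" else 0.0 for i in xs.index]
        result = node_level_regression(
            y, xs, n_perm=config.n_perm_node, seed=config.seed
        )
        (out / "node_regression.json").write_text(
            json.dumps(result.to_dict(), indent=2, default=_jsonable),
            encoding="utf-8",
        )
        _record("node_regression", out / "node_regression.json")

    # ---- GLMM --------------------------------------------------------
    if "glmm" in config.stages:
        table = _sequence_table(events, observed, by_id, kin_pairs, scans, ids)
        table.to_csv(out / "sequence_table.csv", index=False)
        _record("sequence_table", out / "sequence_table.csv")
        spec = GlmmSpec(
            response=config.glmm_response,
            family="binomial_logit",
            fixed_effects=config.glmm_effects,
            group="focal_id",
        )
        fit = fit_glmm(table, spec)
        tidy = fit.estimates.reset_index(names="term")
        tidy["random_intercept_var"] = fit.random_intercept_var
        tidy["n_obs"] = fit.n_obs
        tidy["n_groups"] = fit.n_groups
        tidy["converged"] = fit.converged
        tidy.to_csv(out / "glmm_coefficients.csv", index=False)
        _record("glmm_coefficients", out / "glmm_coefficients.csv")

    manifest["outputs"] = {
        name: {"file": fname, "sha256": _sha256(out / fname)}
        for name, fname in outputs.items()
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_jsonable), encoding="utf-8"
    )
    return manifest


def _sequence_table(events, repertoires, by_id, kin_pairs, scans, ids) -> pd.DataFrame:
    """One row per gesture sequence: homogeneity, dyad attributes, rates."""
    prox = rates_table(scans, ids, ["proximity"]).set_index(["id_a", "id_b"])
    rows = []
    for seq_id, seq_events in sequences_by_id(events).items():
        cls = classify_sequence(seq_events, repertoires)
        if cls is None:
            continue
        signaller = by_id[cls.signaller_id]
        recipient = by_id.get(cls.recipient_id)
        if recipient is None:
            continue
        attrs = score_dyad_attributes(signaller, recipient, kin_pairs)
        try:
            rate = float(
                prox.loc[(cls.signaller_id, cls.recipient_id), "minutes_per_hour"]
            )
        except KeyError:
            rate = float("nan")
        rows.append(
            {
                "sequence_id": seq_id,
                "focal_id": cls.signaller_id,
                "recipient_id": cls.recipient_id,
                "homogeneous_present": 1.0 if cls.homog_repertoire_size > 0 else 0.0,
                "heterogeneous_present": 1.0
                if cls.heterog_repertoire_size > 0
                else 0.0,
                "homog_repertoire_size": cls.homog_repertoire_size,
                "heterog_repertoire_size": cls.heterog_repertoire_size,
                "same_sex": 1.0 if attrs.same_sex else 0.0,
                "same_age_class": (
                    float("nan")
                    if attrs.same_age_class is None
                    else float(attrs.same_age_class)
                ),
                "reproductively_active": 1.0 if attrs.reproductively_active else 0.0,
                "maternal_kin": 1.0 if attrs.maternal_kin else 0.0,
                "proximity_rate": rate,
            }
        )
    return pd.DataFrame(rows)
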