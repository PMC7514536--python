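"""End-to-end analysis runs: network → prediction → ranking → rule mining.

A run is described by a :class:`RunConfig` (loadable from YAML), executed by
:func:`run_analysis`, and leaves behind a plain-text report bundle:

* ``prediction.json``   — variance-node risk given the configured evidence,
                          plus per-node marginals where computable;
* ``ranking.csv``       — diagnostic posterior ranking of all targets;
* ``ranking_primary.csv`` / ``ranking_secondary.csv`` — the same split by
                          layer, mirroring how primary and secondary risk
                          factors are reported separately;
* ``rules_<preset>.csv`` — mined association rules per configured preset;
* ``manifest.json``     — seed, thresholds, package/library versions.

Everything is CSV/JSON on purpose: outputs adjacent to clinical decisions
should be auditable with a text editor.  Any number computed through an
UNSPECIFIED placeholder table is accompanied by an explicit warning line in
the report.  Reports are regenerable bit-for-bit from the manifest, apart
from the manifest's own timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .inference import diagnostic_ranking, marginal, predict_variance
from .mining import (
    AssociationRule,
    PRESETS,
    Transaction,
    mine_protocol,
    read_item_classes,
    read_transactions,
    rules_to_frame,
)
from .network import UnspecifiedTableError, load_network, validate_network

__all__ = ["RunConfig", "StageError", "run_analysis", "explain_rule"]

logger = logging.getLogger(__name__)

#: Probabilities in reports are rounded to four decimals, matching the
#: precision the published tables use; internal values stay full precision.
REPORT_DECIMALS = 4


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one analysis run needs, suitable for YAML round-trips."""

    network: str = "pph"
    evidence: dict[str, str] = field(default_factory=dict)
    targets: list[str] | None = None
    mining: list[dict] = field(default_factory=list)  # {preset, transactions, classes?}
    outdir: str = "cpv-run"
    seed: int = 0
    allow_unspecified: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)


def _round_dist(dist: Mapping[str, float]) -> dict[str, float]:
    return {s: round(p, REPORT_DECIMALS) for s, p in dist.items()}


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory results and the paths written.
    Failures are re-raised as :class:`StageError` naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(outdir), "paths": {}}
    collected_warnings: list[str] = []

    # -- stage: network ------------------------------------------------------
    try:
        net = load_network(config.network)
    except Exception as e:
        raise StageError("network", str(e)) from e
    problems = validate_network(net)
    if problems:
        raise StageError("network", "validation failed: " + "; ".join(problems))
    bundle["network"] = net

    evidence = dict(config.evidence)
    for nid, state in evidence.items():
        if nid not in net.nodes:
            raise StageError("network", f"evidence names unknown node {nid!r}")
        if state not in net.nodes[nid].states:
            raise StageError(
                "network", f"evidence state {state!r} invalid for node {nid!r}"
            )

    # -- stage: prediction ---------------------------------------------------
    prediction: dict = {"evidence": evidence, "seed": config.seed}
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            marginals: dict[str, dict[str, float]] = {}
            skipped: list[str] = []
            for nid in net.topological_order():
                try:
                    marginals[nid] = _round_dist(
                        marginal(net, nid, allow_unspecified=config.allow_unspecified)
                    )
                except UnspecifiedTableError:
                    skipped.append(nid)
            prediction["marginals"] = marginals
            if skipped:
                prediction["marginals_skipped_unspecified"] = skipped
            try:
                vnode = net.variance_node()
            except ValueError:
                vnode = None
            if vnode is not None and evidence:
                try:
                    prediction["variance_node"] = vnode
                    prediction["p_variance_state1"] = round(
                        predict_variance(
                            net, evidence, allow_unspecified=config.allow_unspecified
                        ),
                        REPORT_DECIMALS,
                    )
                except UnspecifiedTableError as e:
                    prediction["variance_prediction_skipped"] = str(e)
        collected_warnings += [str(w.message) for w in caught]
    except StageError:
        raise
    except Exception as e:
        raise StageError("prediction", str(e)) from e
    prediction["warnings"] = sorted(set(collected_warnings))
    pred_path = outdir / "prediction.json"
    pred_path.write_text(json.dumps(prediction, indent=1, sort_keys=True) + "\n")
    bundle["paths"]["prediction"] = str(pred_path)
    bundle["prediction"] = prediction

    # -- stage: ranking ------------------------------------------------------
    targets = config.targets
    if targets is None and evidence:
        targets = [n for n in net.topological_order() if n not in evidence]
    if targets:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                ranking = diagnostic_ranking(
                    net, evidence, list(targets),
                    allow_unspecified=config.allow_unspecified,
                )
            collected_warnings += [str(w.message) for w in caught]
        except Exception as e:
            raise StageError("ranking", str(e)) from e
        frame = ranking.to_frame(net)
        frame["posterior_state1"] = frame["posterior_state1"].round(REPORT_DECIMALS)
        rank_path = outdir / "ranking.csv"
        frame.to_csv(rank_path, index=False)
        bundle["paths"]["ranking"] = str(rank_path)
        for layer in ("primary", "secondary"):
            sub = frame[frame["layer"] == layer]
            if len(sub):
                p = outdir / f"ranking_{layer}.csv"
                sub.to_csv(p, index=False)
                bundle["paths"][f"ranking_{layer}"] = str(p)
        bundle["ranking"] = ranking

    # -- stage: mining -------------------------------------------------------
    mined: dict[str, list[AssociationRule]] = {}
    for job in config.mining:
        preset = job.get("preset")
        tx_path = job.get("transactions")
        try:
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r}")
            if not tx_path or not Path(tx_path).exists():
                raise FileNotFoundError(f"transactions file {tx_path!r} not found")
            transactions = read_transactions(tx_path)
            classes = (
                read_item_classes(job["classes"]) if job.get("classes") else None
            )
            rules = mine_protocol(transactions, preset, item_classes=classes)
        except Exception as e:
            raise StageError("mining", f"preset {preset!r}: {e}") from e
        mined[preset] = rules
        p = outdir / f"rules_{preset}.csv"
        rules_to_frame(rules).to_csv(p, index=False)
        bundle["paths"][f"rules_{preset}"] = str(p)
    if mined:
        bundle["rules"] = mined

    # -- manifest ------------------------------------------------------------
    import networkx
    import numpy

    manifest = {
        "cpv_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "network": net.metadata.get("name", config.network),
        "mining_thresholds": {
            name: {
                "min_support": PRESETS[name].min_support,
                "min_confidence": PRESETS[name].min_confidence,
                "min_lift": PRESETS[name].min_lift,
            }
            for name in (job.get("preset") for job in config.mining)
            if name in PRESETS
        },
        "warnings": sorted(set(collected_warnings)),
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    bundle["paths"]["manifest"] = str(man_path)
    bundle["warnings"] = manifest["warnings"]
    return bundle


def explain_rule(
    rule: AssociationRule, transactions: Sequence[Transaction]
) -> dict:
    """Audit one rule against raw transactions.

    Lists the case ids matching the antecedent (and those also matching the
    consequent) and recomputes support, confidence and lift from scratch;
    flags any mismatch with the rule's stored metrics.
    """
    vocab = {i for t in transactions for i in t.items}
    unknown = (rule.antecedent | rule.consequent) - vocab
    if unknown:
        raise KeyError(f"rule items {sorted(unknown)} not present in transactions")
    n = len(transactions)
    ant_cases = [t.case_id for t in transactions if rule.antecedent <= t.items]
    both_cases = [
        t.case_id
        for t in transactions
        if (rule.antecedent | rule.consequent) <= t.items
    ]
    cons_count = sum(1 for t in transactions if rule.consequent <= t.items)
    support = len(both_cases) / n
    confidence = len(both_cases) / len(ant_cases) if ant_cases else float("nan")
    lift = confidence / (cons_count / n) if cons_count else float("nan")
    tol = 1e-12
    mismatches = [
        name
        for name, stored, fresh in (
            ("support", rule.support, support),
            ("confidence", rule.confidence, confidence),
            ("lift", rule.lift, lift),
        )
        if not (abs(stored - fresh) <= tol)
    ]
    return {
        "rule": str(rule),
        "n_transactions": n,
        "antecedent_cases": ant_cases,
        "matching_cases": both_cases,
        "recomputed": {"support": support, "confidence": confidence, "lift": lift},
        "stored": {
            "support": rule.support,
            "confidence": rule.confidence,
            "lift": rule.lift,
        },
        "mismatches": mismatches,
        "consistent": not mismatches,
    }
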