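"""Benchmark harness: full-model statistics and end-to-end reduction reports.

Reproduces the summary-table statistics of a reduction case study (reaction
and metabolite counts, degrees of freedom, conservation relations, enzyme
subsets, per-scenario maximal objective values) for the full, pruned, and
compressed variants of a user-supplied genome-scale model.  Genome-scale
inputs are external downloads: nothing is fetched automatically and the
harness is opt-in (`netreduce bench`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import lp
from .compression import bsr_diff, compress, detect_subsets
from .io import read_protection_spec, read_sbml
from .model import MetabolicModel, ModelError, ProtectionSpec
from .pruning import prune

ROW_LABELS = (
    "# reactions",
    "# int. metabolites",
    "# ext. metabolites",
    "degrees of freedom",
    "# conservation relations",
    "# enzyme subsets (# containing reactions)",
)


def model_statistics(
    model: MetabolicModel,
    spec: ProtectionSpec | None = None,
    count_subsets: bool = True,
) -> dict[str, object]:
    """Summary-table statistics for one model variant."""
    stats: dict[str, object] = {
        "# reactions": model.n_reactions,
        "# int. metabolites": model.n_metabolites,
        "# ext. metabolites": len(model.external_species),
        "degrees of freedom": lp.dof(model),
        "# conservation relations": lp.conservation_relations(model)[0],
    }
    if count_subsets:
        smap = detect_subsets(model, spec)
        multi = [s for s in smap.subsets if len(s.members) > 1]
        stats["# enzyme subsets (# containing reactions)"] = (
            f"{len(multi)} ({sum(len(s.members) for s in multi)})"
        )
    else:
        stats["# enzyme subsets (# containing reactions)"] = ""
    if spec is not None and np.any(model.objective):
        for sc in spec.scenarios:
            res = lp.fba(model, None, sc)
            stats[f"mu_max ({sc.name})"] = (
                round(res.objective_value, 4)
                if res.status == "optimal"
                else res.status
            )
    return stats


def run_benchmark(
    model_path: str | Path,
    spec_path: str | Path,
    seed: int = 0,
    do_compress: bool = True,
    biomass_reaction: str | None = None,
) -> dict[str, object]:
    """Reduce a user-supplied SBML model and report summary statistics.

    Returns a dict with a ``table`` DataFrame (rows mirror the standard
    summary-table labels, columns full/pruned/compressed), the reduction
    objects, and a BSR comparison when a biomass reaction is identifiable.
    Raises :class:`ModelError` with provenance guidance when the files are
    missing; no download is ever attempted.
    """
    model_path, spec_path = Path(model_path), Path(spec_path)
    if not model_path.exists():
        raise ModelError(
            f"benchmark model {model_path} not found. Benchmarks run on "
            "externally obtained genome-scale SBML models (e.g. an "
            "iAF1260-derived E. coli model or a Synechocystis sp. PCC 6803 "
            "reconstruction); download one manually and pass its path — "
            "nothing is fetched automatically."
        )
    if not spec_path.exists():
        raise ModelError(f"protection spec {spec_path} not found")
    model = read_sbml(model_path)
    spec = read_protection_spec(spec_path, model)

    result = prune(model, spec, seed=seed)
    columns: dict[str, dict[str, object]] = {
        "full": model_statistics(model, spec, count_subsets=model.n_reactions <= 3000),
        "pruned": model_statistics(result.model, spec),
    }
    out: dict[str, object] = {"prune_result": result}
    compressed = None
    if do_compress:
        compressed = compress(result.model, spec)
        columns["compressed"] = model_statistics(compressed.model, spec)
        out["compressed"] = compressed

    if biomass_reaction is None and np.any(model.objective):
        j = int(np.nonzero(model.objective)[0][0])
        biomass_reaction = model.reaction_ids[j]
    if (
        biomass_reaction is not None
        and compressed is not None
        and biomass_reaction in compressed.model.reaction_ids
    ):
        out["bsr_diff"] = bsr_diff(
            model, biomass_reaction, compressed, biomass_reaction,
            names=("full", "compressed"),
        )

    table = pd.DataFrame(columns)
    out["table"] = table
    return out
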