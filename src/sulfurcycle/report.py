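"""Report assembly: flux-network summary with provenance, capability
matrices, and layer panels.

Every derived number in a report carries the addends it was computed from,
so a reader can recompute it exactly from the report alone.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .fluxes import FluxNetwork, RateEstimate, round_report


def flux_report(network: FluxNetwork) -> dict:
    """Machine-readable flux summary; each edge lists its provenance."""
    report = network.to_dict()
    report["derived"] = {
        "biological_sulfide_oxidation": {
            "value": round_report(network.edge_value("sulfide", "zerovalent_sulfur")),
            "addends": next(
                r.provenance for s, k, r in network.edges
                if (s, k) == ("sulfide", "zerovalent_sulfur")
            ),
        },
        "zvs_oxidation_to_sulfite": {
            "value": round_report(network.zvs_to_sulfite),
            "addends": next(
                r.provenance for s, k, r in network.edges
                if (s, k) == ("zerovalent_sulfur", "sulfite")
            ),
        },
        "zvs_unknown_fate": {
            "value": round_report(network.unknown_fate),
            "addends": {
                "zvs_production": next(
                    r.provenance for s, k, r in network.edges
                    if (s, k) == ("zerovalent_sulfur", "sulfite")
                ),
            },
        },
    }
    return report


def flux_summary_text(network: FluxNetwork) -> str:
    lines = [
        f"Sulfur mass-balance flux network ({network.convention})",
        "  rates in µmol/h/g wet sediment",
    ]
    for s, k, r in network.edges:
        lines.append(f"  {s} -> {k}: {r.rounded} ({r.component})")
    lines.append(f"  zerovalent sulfur -> unknown fate: {round_report(network.unknown_fate)}")
    lines.append(
        "  budget residual at zerovalent sulfur: "
        f"{network.balance_residuals['zerovalent_sulfur']:.2e}"
    )
    return "\n".join(lines)


def run_manifest(inputs: dict, parameters: dict, seed: int | None) -> dict:
    """Machine-readable record of a run: inputs (with content hashes for
    files that exist), parameters, seed, and versions."""
    hashed = {}
    for name, value in inputs.items():
        entry = {"value": str(value)}
        p = Path(str(value))
        if p.is_file():
            entry["sha256"] = hashlib.sha256(p.read_bytes()).hexdigest()
        hashed[name] = entry
    return {
        "package": "sulfurcycle",
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "seed": seed,
        "inputs": hashed,
        "parameters": parameters,
    }


def manifest_hash(manifest: dict) -> str:
    """Stable hash of a manifest, ignoring the timestamp."""
    stripped = {k: v for k, v in manifest.items() if k != "timestamp"}
    return hashlib.sha256(
        json.dumps(stripped, sort_keys=True, default=str).encode()
    ).hexdigest()


def capability_matrix_text(per_taxon: pd.DataFrame, community: dict) -> str:
    lines = [
        "Community capability summary",
        f"  genomes: {community['n_genomes']}",
        f"  with >=1 sulfur-oxidation route: {community['n_capable']} "
        f"({community['pct_capable']:.1f}%)",
        f"  complete Sat-AprAB: {community['n_sat_aprab_complete']} "
        f"({community['pct_sat_aprab_complete']:.1f}%)",
        "",
        per_taxon.to_string(index=False, max_colwidth=24),
    ]
    return "\n".join(lines)
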