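"""Golden-trace regression fixtures.

Small, fully-seeded reference simulations (single-item encode/delay/probe,
two-item retro-cue, pulse trial) for every model variant, stored as tidy
CSV traces plus a JSON manifest with the configuration hash.  Regenerating
with the same seed must reproduce the stored traces bit-for-bit; the test
suite regenerates them in memory and compares.
"""

from __future__ import annotations

import json
from pathlib import Path

from .network import init_network
from .params import VARIANTS, ModelParams
from .protocols import StimulusItem, build_trial, run_script


def fixture_specs():
    """The (name, builder) pairs covered by the fixture bundle."""

    def one_item(p):
        return build_trial([StimulusItem((0, 1, 2))], p, probe_item=0)

    def retrocue(p):
        items = [StimulusItem((0, 1, 2)), StimulusItem((1, 2, 3))]
        return build_trial(items, p, probe_item=0, delay_steps=300,
                           retrocue=(0, 0), cue_time=100)

    def pulse(p):
        items = [StimulusItem((0, 1, 2)), StimulusItem((1, 2, 3))]
        return build_trial(items, p, probe_item=0, delay_steps=300,
                           pulse=(4.0, 10, 150))

    return [("one_item", one_item), ("retrocue", retrocue), ("pulse", pulse)]


def generate_fixtures(params: ModelParams, seed: int = 0):
    """Build the fixture bundle in memory.

    Returns a dict mapping fixture name to its tidy trace DataFrame; covers
    every variant with the single-item script plus the full battery for the
    full model.
    """
    bundle = {}
    for variant in VARIANTS:
        p = params.replace(variant=variant)
        specs = fixture_specs() if variant == "full" else fixture_specs()[:1]
        for name, builder in specs:
            script = builder(p)
            state = init_network(p, seed)
            state, trace = run_script(state, script, p)
            key = f"{variant}__{name}"
            bundle[key] = trace.to_dataframe(run_id=key)
    return bundle


def write_fixtures(params: ModelParams, seed: int, out_dir) -> Path:
    """Write the bundle and a manifest (config hash, seed, row counts)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_fixtures(params, seed)
    manifest = {"seed": int(seed), "config_hash": params.config_hash(), "traces": {}}
    for key, df in bundle.items():
        path = out / f"{key}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["traces"][key] = {"rows": int(len(df)), "file": path.name}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
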