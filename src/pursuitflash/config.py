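"""Default configuration and YAML loading for the analysis pipeline.

The config is a plain nested dict; :func:`load_config` merges a YAML file
over the defaults.  The statistical test battery is declarative: each entry
names the two PSE cells to compare (or a difference tested against zero)
and the number of tails, so the science lives in data rather than code.
"""

from __future__ import annotations

import copy

import yaml

#: Paired comparisons of PSE cells run by the pipeline.  ``a``/``b`` select
#: cells of the PSE table by (task, soa_ms, placement); fixation cells have
#: placement None.
DEFAULT_TEST_BATTERY = [
    {"label": "negSOA ahead vs fixation", "tails": "two",
     "a": ["pursuit_relative", -200, "ahead"], "b": ["fixation_relative", -200, None]},
    {"label": "negSOA behind vs fixation", "tails": "two",
     "a": ["pursuit_relative", -200, "behind"], "b": ["fixation_relative", -200, None]},
    {"label": "negSOA ahead vs behind", "tails": "two",
     "a": ["pursuit_relative", -200, "ahead"], "b": ["pursuit_relative", -200, "behind"]},
    {"label": "fixation posSOA vs negSOA", "tails": "one",
     "a": ["fixation_relative", 200, None], "b": ["fixation_relative", -200, None]},
    {"label": "posSOA ahead vs fixation", "tails": "two",
     "a": ["pursuit_relative", 200, "ahead"], "b": ["fixation_relative", 200, None]},
    {"label": "posSOA behind vs fixation", "tails": "two",
     "a": ["pursuit_relative", 200, "behind"], "b": ["fixation_relative", 200, None]},
    {"label": "posSOA ahead vs behind", "tails": "two",
     "a": ["pursuit_relative", 200, "ahead"], "b": ["pursuit_relative", 200, "behind"]},
    {"label": "ahead posSOA vs negSOA", "tails": "two",
     "a": ["pursuit_relative", 200, "ahead"], "b": ["pursuit_relative", -200, "ahead"]},
    {"label": "behind posSOA vs negSOA", "tails": "two",
     "a": ["pursuit_relative", 200, "behind"], "b": ["pursuit_relative", -200, "behind"]},
]

DEFAULT_CONFIG = {
    "seed": 0,
    "n_subjects": 8,
    "counts": {
        "pursuit_relative": 150,
        "fixation_relative": 150,
        "pursuit_absolute": 50,
        "coarse_per_offset": 3,
    },
    "observer": {},  # overrides for synthetic.make_observer
    "screen": {
        "width_cm": 120.0,
        "height_cm": 90.0,
        "viewing_distance_cm": 70.0,
        "resolution_px": [1152, 864],
        "refresh_hz": 120.0,
    },
    "qc": {"saccade_velocity_threshold": 30.0},
    "n_boot": 199,  # bootstrap resamples per PSE CI in the pipeline
    "distance_metric": "perpendicular",  # or 'vertical', for the model d
    "alpha": 0.05,
    "tests": DEFAULT_TEST_BATTERY,
    "outdir": "pursuitflash_out",
    # paths of an existing dataset; when absent the pipeline generates one
    "trials_path": None,
    "traces_path": None,
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path=None, overrides: dict = None) -> dict:
    """Defaults, overlaid with a YAML file and then explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
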