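"""The canonical registry of 53 day-wise derived sensing variables.

The variables span four behavioral channels — activity, sleep, mobility
and communication (screen use feeds both activity context and sleep).
Window suffixes refer to the canonical clock windows (am/day/eve/night);
``peak``/``offpeak`` split communication at the configurable peak calling
hours.  The registry is an ordered tuple of names; pipelines may pass a
custom subset or extension anywhere a ``registry`` argument is accepted.
"""

from __future__ import annotations

_WINDOWS = ("am", "day", "eve", "night")

ACTIVITY_FEATURES = tuple(
    [f"activity_{w}" for w in ("total",) + _WINDOWS]
    + [f"activity_frac_{w}" for w in ("total",) + _WINDOWS]
)

SCREEN_FEATURES = tuple(f"screen_on_{w}" for w in ("total",) + _WINDOWS)

SLEEP_FEATURES = (
    "sleep_minutes",
    "night_screen_ons",
    "night_stationary_fraction",
    "sleep_efficiency",
    "wake_episodes",
)

MOBILITY_FEATURES = tuple(
    [f"locations_{w}" for w in ("total",) + _WINDOWS]
    + [f"distance_{w}" for w in ("total",) + _WINDOWS]
)

_CALL_BASE = (
    "calls_total",
    "calls_made",
    "calls_received",
    "calls_missed",
    "call_duration_total",
    "call_duration_mean",
    "people_called",
)

COMMUNICATION_FEATURES = (
    _CALL_BASE
    + ("call_duration_made", "call_duration_received")
    + tuple(f"{f}_peak" for f in _CALL_BASE)
    + tuple(f"{f}_offpeak" for f in _CALL_BASE)
)

#: The default 53-variable registry, ordered by channel.
DEFAULT_REGISTRY: tuple[str, ...] = (
    ACTIVITY_FEATURES + SCREEN_FEATURES + SLEEP_FEATURES + MOBILITY_FEATURES + COMMUNICATION_FEATURES
)

#: Channel membership, used for documentation and channel-wise selection.
FEATURE_CHANNELS: dict[str, str] = {}
for _name in ACTIVITY_FEATURES:
    FEATURE_CHANNELS[_name] = "activity"
for _name in SCREEN_FEATURES:
    FEATURE_CHANNELS[_name] = "screen"
for _name in SLEEP_FEATURES:
    FEATURE_CHANNELS[_name] = "sleep"
for _name in MOBILITY_FEATURES:
    FEATURE_CHANNELS[_name] = "mobility"
for _name in COMMUNICATION_FEATURES:
    FEATURE_CHANNELS[_name] = "communication"

assert len(DEFAULT_REGISTRY) == 53
assert len(set(DEFAULT_REGISTRY)) == 53
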