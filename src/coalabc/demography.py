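"""Three-population divergence-with-founder-bottleneck demographic models.

One coalescent generation is equated to one calendar year, so event times
are interchangeable between generations and years.  Each derived population
undergoes a founder episode (size ``NF_*`` for ``bottleneck_dur``
generations immediately after founding, forward in time); exactly one deme
per model stays at constant size throughout.

Model topologies (backward in time):

- ``mesoamerican`` -- MW constant; AW merges into MW at T1, PhI at T2.
- ``phi``          -- PhI constant; AW merges into PhI at T1, MW at T2.
- ``protovulgaris``-- unsampled ancestor ANC constant; MW and AW merge into
  ANC at T1, PhI merges into ANC at T2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

MODEL_NAMES = ("mesoamerican", "phi", "protovulgaris")
DEMES = ("MW", "AW", "PhI")

#: diploid sample sizes of the genotyped panel
FULL_PROFILE = {"MW": 157, "AW": 77, "PhI": 12}
#: scaled-down profile used throughout the test suite
REDUCED_PROFILE = {"MW": 20, "AW": 10, "PhI": 6}


@dataclass
class DemographicParameters:
    """Sizes are diploid effective sizes; times in generations (= years)."""

    N_MW: float = 50_000.0
    N_AW: float = 50_000.0
    N_PhI: float = 50_000.0
    N_ANC: float = 50_000.0
    NF_MW: float = 500.0
    NF_AW: float = 500.0
    NF_PhI: float = 500.0
    T1: float = 87_410.0  # AW divergence
    T2: float = 373_060.0  # PhI divergence
    mu: float = 1e-8
    bottleneck_dur: float = 100.0

    def __post_init__(self) -> None:
        for name in ("N_MW", "N_AW", "N_PhI", "N_ANC", "NF_MW", "NF_AW", "NF_PhI"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("T1", "T2", "bottleneck_dur"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class Epoch:
    """Deme size on the backward-time interval [t_start, t_end)."""

    t_start: float
    t_end: float
    size: float


@dataclass
class MergeEvent:
    """At backward time ``time`` all lineages of ``derived`` move to ``source``."""

    time: float
    derived: str
    source: str


@dataclass
class DemographicModel:
    name: str
    demes: list[str]  # sampled demes first, then any unsampled ancestor
    sample_demes: list[str]
    constant_deme: str
    epochs: dict[str, list[Epoch]] = field(default_factory=dict)
    events: list[MergeEvent] = field(default_factory=list)

    def size_profile(self, deme: str) -> list[Epoch]:
        return self.epochs[deme]

    def root_deme(self) -> str:
        """The deme every sampled lineage reaches backward in time."""
        current = {d: d for d in self.demes}
        for ev in sorted(self.events, key=lambda e: e.time):
            for k, v in current.items():
                if v == ev.derived:
                    current[k] = ev.source
        roots = {current[d] for d in self.sample_demes}
        if len(roots) != 1:
            raise ValueError(f"model {self.name}: lineages do not reach one root")
        return roots.pop()

    def describe(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "demes": self.demes,
                "constant_deme": self.constant_deme,
                "events": [asdict(e) for e in sorted(self.events, key=lambda e: e.time)],
                "epochs": {d: [asdict(e) for e in eps] for d, eps in self.epochs.items()},
            },
            indent=2,
        )


def _derived_epochs(
    n_current: float, nf: float, t_merge: float, dur: float
) -> list[Epoch]:
    """Backward epochs of a derived deme founded at t_merge with founder size
    nf held for dur generations after founding (forward time)."""
    t_grow = max(t_merge - dur, 0.0)
    eps = []
    if t_grow > 0:
        eps.append(Epoch(0.0, t_grow, n_current))
        eps.append(Epoch(t_grow, t_merge, nf))
    else:  # bottleneck spans the whole existence of the deme
        eps.append(Epoch(0.0, t_merge, nf))
    eps.append(Epoch(t_merge, np.inf, nf))  # unused past merge; kept for safety
    return eps


def build_model(
    name: str,
    params: DemographicParameters,
) -> DemographicModel:
    """Instantiate one of the three divergence topologies.

    Events are returned sorted by time, so parameter draws with T2 < T1 under
    topologies where the two merges are independent remain well defined.
    """
    p = params
    if name == "mesoamerican":
        epochs = {
            "MW": [Epoch(0.0, np.inf, p.N_MW)],
            "AW": _derived_epochs(p.N_AW, p.NF_AW, p.T1, p.bottleneck_dur),
            "PhI": _derived_epochs(p.N_PhI, p.NF_PhI, p.T2, p.bottleneck_dur),
        }
        events = [
            MergeEvent(p.T1, "AW", "MW"),
            MergeEvent(p.T2, "PhI", "MW"),
        ]
        model = DemographicModel(
            name=name,
            demes=list(DEMES),
            sample_demes=list(DEMES),
            constant_deme="MW",
            epochs=epochs,
            events=sorted(events, key=lambda e: e.time),
        )
    elif name == "phi":
        epochs = {
            "PhI": [Epoch(0.0, np.inf, p.N_PhI)],
            "AW": _derived_epochs(p.N_AW, p.NF_AW, p.T1, p.bottleneck_dur),
            "MW": _derived_epochs(p.N_MW, p.NF_MW, p.T2, p.bottleneck_dur),
        }
        events = [
            MergeEvent(p.T1, "AW", "PhI"),
            MergeEvent(p.T2, "MW", "PhI"),
        ]
        model = DemographicModel(
            name=name,
            demes=list(DEMES),
            sample_demes=list(DEMES),
            constant_deme="PhI",
            epochs=epochs,
            events=sorted(events, key=lambda e: e.time),
        )
    elif name == "protovulgaris":
        epochs = {
            "MW": _derived_epochs(p.N_MW, p.NF_MW, p.T1, p.bottleneck_dur),
            "AW": _derived_epochs(p.N_AW, p.NF_AW, p.T1, p.bottleneck_dur),
            "PhI": _derived_epochs(p.N_PhI, p.NF_PhI, p.T2, p.bottleneck_dur),
            "ANC": [Epoch(0.0, np.inf, p.N_ANC)],
        }
        events = [
            MergeEvent(p.T1, "MW", "ANC"),
            MergeEvent(p.T1, "AW", "ANC"),
            MergeEvent(p.T2, "PhI", "ANC"),
        ]
        model = DemographicModel(
            name=name,
            demes=list(DEMES) + ["ANC"],
            sample_demes=list(DEMES),
            constant_deme="ANC",
            epochs=epochs,
            events=sorted(events, key=lambda e: e.time),
        )
    else:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    model.root_deme()  # raises if any sampled lineage is orphaned
    return model


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

_FAMILIES = ("uniform", "loguniform", "fixed")


@dataclass
class PriorSpec:
    """Per-parameter prior: {name: ("uniform"|"loguniform", low, high) or
    ("fixed", value)}.

    The shipped defaults are reconstructions chosen to bracket plausible
    posteriors; they are NOT a published prior table.
    """

    params: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, spec in self.params.items():
            fam = spec[0]
            if fam not in _FAMILIES:
                raise ValueError(f"{name}: unknown prior family {fam!r}")
            if fam == "fixed":
                if len(spec) != 2:
                    raise ValueError(f"{name}: fixed prior takes one value")
            else:
                _, lo, hi = spec
                if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                    raise ValueError(f"{name}: bounds must be finite with low < high")
                if fam == "loguniform" and lo <= 0:
                    raise ValueError(f"{name}: log-uniform needs positive bounds")

    @classmethod
    def default(cls) -> "PriorSpec":
        sizes = ("N_MW", "N_AW", "N_PhI", "N_ANC")
        founders = ("NF_MW", "NF_AW", "NF_PhI")
        p: dict[str, tuple] = {}
        for s in sizes:
            p[s] = ("loguniform", 1e3, 1e6)
        for f in founders:
            p[f] = ("loguniform", 10.0, 1e4)
        p["T1"] = ("uniform", 1e4, 5e5)
        p["T2"] = ("uniform", 5e4, 2e6)
        p["mu"] = ("fixed", 1e-8)
        p["bottleneck_dur"] = ("fixed", 100.0)
        return cls(p)

    def free_names(self) -> list[str]:
        return [n for n, s in self.params.items() if s[0] != "fixed"]


def sample_prior(
    spec: PriorSpec, rng: np.random.Generator, enforce_t2_gt_t1: bool = False
) -> DemographicParameters:
    """One draw per parameter from the prior.

    ``enforce_t2_gt_t1`` rejects draws with T2 <= T1 (off by default; the
    split times are otherwise independent).
    """
    required = set(DemographicParameters().as_dict())
    missing = required - set(spec.params)
    if missing:
        raise ValueError(f"prior spec missing parameters: {sorted(missing)}")
    for _ in range(10_000):
        draw: dict[str, float] = {}
        for name, s in spec.params.items():
            fam = s[0]
            if fam == "fixed":
                draw[name] = float(s[1])
            elif fam == "uniform":
                draw[name] = float(rng.uniform(s[1], s[2]))
            else:  # loguniform
                draw[name] = float(np.exp(rng.uniform(np.log(s[1]), np.log(s[2]))))
        if enforce_t2_gt_t1 and draw["T2"] <= draw["T1"]:
            continue
        return DemographicParameters(**draw)
    raise RuntimeError("prior truncation rejected 10,000 consecutive draws")
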