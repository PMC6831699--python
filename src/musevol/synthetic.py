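"""Synthetic corpora implementing the generative assumptions of the
evolutionary model, so every other layer is testable without any
copyrighted corpus.

Per generation t with creator model Beta(a_t, b_t), each piece draws a
frequency theta from the model, a note count N uniformly from the
configured range (musical pieces typically run 10^2 to 10^3 notes), and
an event count Binomial(N, theta); the observed per-piece frequency is
count / N.  The per-piece events are Bernoulli per note slot: the model
abstracts data chunks to theta directly, so binomial sampling is the
minimal faithful data layer.

Also provides note-level fixture writers (note-list and optional MIDI)
whose extracted interval sequences are known by construction, and an
end-to-end parameter-recovery harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import smf
from .corpus import window_series
from .distributions import (
    BetaParams,
    LogNormalParams,
    MomentPair,
    lognormal_from_moments,
    moments_from_beta,
)
from .errors import InvalidParameterError
from .fitting import FitResult, fit
from .logpotential import iterate_logpotential
from .sce import SelectionParams, iterate
from .trajectory import TimeMap, Trajectory

__all__ = [
    "SyntheticCorpusConfig",
    "simulate_corpus",
    "make_note_fixtures",
    "NoteFixturePlan",
    "recovery_experiment",
    "RecoveryReport",
]


@dataclass
class SyntheticCorpusConfig:
    """Conditions for a synthetic corpus draw.

    ``trajectory`` holds one creator model per generation; generation t
    maps to year start_year + t * years_per_generation.
    """

    trajectory: Sequence[BetaParams]
    pieces_per_generation: int
    note_count_range: tuple[int, int] = (100, 1000)
    seed: int = 0
    start_year: float = 1500.0
    years_per_generation: float = 25.0

    def __post_init__(self) -> None:
        if len(self.trajectory) == 0:
            raise InvalidParameterError("trajectory must be nonempty")
        if self.pieces_per_generation < 1:
            raise InvalidParameterError("pieces_per_generation must be positive")
        lo, hi = self.note_count_range
        if not (2 <= lo <= hi <= 10**5):
            raise InvalidParameterError(f"note_count_range {self.note_count_range} outside [2, 1e5]")
        if self.years_per_generation <= 0:
            raise InvalidParameterError("years_per_generation must be positive")


def simulate_corpus(config: SyntheticCorpusConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic corpus; fully reproducible from the seed.

    Returns ``(features, metadata)``: features has one row per piece
    with columns piece_id, composer, year, n_notes, count, freq (the
    schema consumed by the corpus statistics layer); metadata repeats
    piece_id, composer, year.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.note_count_range
    rows = []
    for t, params in enumerate(config.trajectory):
        year = config.start_year + t * config.years_per_generation
        composer = f"gen{t:03d}"
        theta = rng.beta(params.a, params.b, size=config.pieces_per_generation)
        n_notes = rng.integers(lo, hi + 1, size=config.pieces_per_generation)
        counts = rng.binomial(n_notes, theta)
        for m in range(config.pieces_per_generation):
            rows.append(
                {
                    "piece_id": f"synth_t{t:03d}_p{m:04d}",
                    "composer": composer,
                    "year": year,
                    "n_notes": int(n_notes[m]),
                    "count": int(counts[m]),
                    "freq": counts[m] / n_notes[m],
                }
            )
    features = pd.DataFrame(rows)
    metadata = features[["piece_id", "composer", "year"]].copy()
    return features, metadata


@dataclass
class NoteFixturePlan:
    """A piece whose extracted features are known by construction.

    Either ``intervals`` (pitch-class intervals in 1..11, realised as a
    monotone pitch line from ``start_pitch``) or explicit ``pitches``;
    optional ``note_values`` attach notated durations.
    """

    piece_id: str
    intervals: Optional[Sequence[int]] = None
    pitches: Optional[Sequence[int]] = None
    note_values: Optional[Sequence[Union[Fraction, str]]] = None
    start_pitch: int = 60

    def realised_pitches(self) -> list[int]:
        if self.pitches is not None:
            return list(self.pitches)
        if self.intervals is None:
            raise InvalidParameterError(f"{self.piece_id}: plan needs intervals or pitches")
        pitches = [self.start_pitch]
        for iv in self.intervals:
            if not 1 <= int(iv) <= 11:
                raise InvalidParameterError(f"{self.piece_id}: interval {iv} outside 1..11")
            step = int(iv)
            # fold down an octave when running out of MIDI range
            nxt = pitches[-1] + step
            if nxt > 127:
                nxt -= 12 * ((nxt - 127 + 11) // 12)
            pitches.append(nxt)
        return pitches


def make_note_fixtures(
    plans: Sequence[NoteFixturePlan],
    out_dir,
    *,
    write_midi: bool = False,
) -> list[Path]:
    """Write note-list files (and optionally MIDI twins) for the plans.

    The note-list writer/reader round trip is exact.  Returns the paths
    written, note-list files first.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for plan in plans:
        pitches = plan.realised_pitches()
        values = None
        if plan.note_values is not None:
            values = [Fraction(v) for v in plan.note_values]
            if len(values) != len(pitches):
                raise InvalidParameterError(f"{plan.piece_id}: {len(values)} note values for {len(pitches)} notes")
        path = out / f"{plan.piece_id}.notes"
        with open(path, "w") as fh:
            fh.write(f"# fixture {plan.piece_id}: synthetic, planted by construction\n")
            onset = Fraction(0)
            for i, p in enumerate(pitches):
                if values is not None:
                    fh.write(f"{onset}\t{p}\t{values[i]}\n")
                    onset += values[i]
                else:
                    fh.write(f"{onset}\t{p}\n")
                    onset += 1
        paths.append(path)
    if write_midi:
        for plan in plans:
            pitches = plan.realised_pitches()
            values = [Fraction(v) for v in plan.note_values] if plan.note_values else [Fraction(1)] * len(pitches)
            events, onset = [], Fraction(0)
            for p, v in zip(pitches, values):
                events.append((onset, p, v))
                onset += v
            mpath = Path(out_dir) / f"{plan.piece_id}.mid"
            smf.write_midi(mpath, events)
            paths.append(mpath)
    return paths


@dataclass
class RecoveryReport:
    """True vs recovered selection coefficients of an end-to-end run."""

    model: str
    true_params: Union[SelectionParams, float]
    fit_result: FitResult
    trajectory: Trajectory
    series: pd.DataFrame
    relative_errors: dict = field(default_factory=dict)


def recovery_experiment(
    model: str,
    true_params: Union[SelectionParams, float],
    *,
    init: Optional[Union[MomentPair, LogNormalParams]] = None,
    generations: int = 16,
    pieces_per_generation: int = 500,
    note_count_range: tuple[int, int] = (100, 1000),
    seed: int = 0,
    noiseless: bool = False,
    grid: int = 9,
    beta_max: float = 20.0,
) -> RecoveryReport:
    """Simulate a trajectory, (optionally) sample a corpus from it,
    window it, fit the generating model, and report true vs recovered
    coefficients.

    ``noiseless=True`` skips corpus sampling and fits the exact model
    moments; otherwise each window of the synthetic corpus corresponds
    to one generation.
    """
    if generations < 1:
        raise InvalidParameterError("generations must be >= 1")
    tm = TimeMap(1500.0, 25.0)
    if model == "sce":
        if init is None:
            init = MomentPair(0.02, 0.01)
        traj = iterate(init, true_params, generations, time_map=tm)
    elif model == "log-potential":
        if init is None:
            init = lognormal_from_moments(0.02, 0.01)
        traj = iterate_logpotential(init, true_params, generations, time_map=tm)
    else:
        raise InvalidParameterError(f"unknown model {model!r}")

    if noiseless:
        series = traj.series()
    else:
        betas = [s.params if isinstance(s.params, BetaParams) else None for s in traj.states]
        if any(p is None for p in betas):
            raise InvalidParameterError("sampled corpora need a beta-parameterised trajectory")
        config = SyntheticCorpusConfig(
            trajectory=betas,
            pieces_per_generation=pieces_per_generation,
            note_count_range=note_count_range,
            seed=seed,
            start_year=tm.start_year,
            years_per_generation=tm.years_per_generation,
        )
        features, _meta = simulate_corpus(config)
        series = window_series(
            features, "freq",
            width=tm.years_per_generation, step=tm.years_per_generation,
            origin=tm.start_year,
        )

    result = fit(model, [series], grid=grid, beta_max=beta_max)
    rel = {}
    if model == "sce":
        for name in ("beta_T", "beta_N"):
            true_v = getattr(true_params, name)
            rec_v = getattr(result.params, name)
            rel[name] = abs(rec_v - true_v) / abs(true_v) if true_v != 0 else abs(rec_v)
    else:
        rel["beta"] = abs(result.params - true_params) / abs(true_params) if true_params != 0 else abs(result.params)
    return RecoveryReport(model, true_params, result, traj, series, rel)
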