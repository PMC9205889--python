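"""End-to-end orchestration of the simulated-study pipeline.

simulate -> merge episodes -> filter participants -> build networks ->
metrics -> CES-D generation -> feature table. Used by the CLI, the test
suite and the acceptance script; each stage remains individually callable
through its own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import analysis, community, netmetrics, preprocess, synthgen
from .synthgen import InteractionLog, Roster, SimConfig

__all__ = ["StudyData", "simulate_study"]


@dataclass
class StudyData:
    """Everything one simulated deployment produces."""

    config: SimConfig
    roster: Roster
    log: InteractionLog
    episodes: pd.DataFrame
    retained: set
    networks: dict
    features: pd.DataFrame  # incl. cesd_total
    cesd: pd.DataFrame


def simulate_study(
    config: SimConfig,
    gap_limit: int = preprocess.GAP_LIMIT_DEFAULT,
    apply_filter: bool | None = None,
    attach_movement: bool | None = None,
) -> StudyData:
    """Run the full pipeline on one generated deployment.

    ``apply_filter`` defaults to True when movement data exist (wear time
    is defined by movement samples); ``attach_movement`` controls whether
    per-episode mean movement columns are computed (defaults to True when
    movement samples exist).
    """
    roster = synthgen.generate_roster(config)
    log = synthgen.generate_interaction_log(roster, config)
    episodes = preprocess.merge_episodes(log.detections, gap_limit)

    have_movement = len(log.movement) > 0
    if attach_movement is None:
        attach_movement = have_movement
    if attach_movement and have_movement:
        episodes = preprocess.episode_movement(episodes, log.movement)

    # wear time is defined by movement-sample coverage, so the exclusion
    # rule is meaningful only when the generator emitted full-day samples
    if apply_filter is None:
        apply_filter = have_movement and config.movement_mode == "full"
    if apply_filter and have_movement:
        wear = preprocess.wear_minutes(log.movement)
        retained = preprocess.filter_participants(episodes, wear)
    else:
        retained = set(roster.persons)

    networks = preprocess.build_networks(
        episodes, roster, retained=retained, n_days=config.n_days
    )
    features = netmetrics.feature_table(networks)
    cesd = synthgen.generate_cesd(features, config)
    features = netmetrics.feature_table(networks, cesd)
    return StudyData(
        config=config,
        roster=roster,
        log=log,
        episodes=episodes,
        retained=retained,
        networks=networks,
        features=features,
        cesd=cesd,
    )
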