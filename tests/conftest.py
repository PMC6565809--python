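"""Shared fixtures: small hand-built networks and walk corpora.

Everything is constructed programmatically; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from infowalk.netcore import (
    ActorProfile,
    InformationWalk,
    ReferralNetwork,
    Visit,
    WalkCorpus,
)


def make_profile(aid: str, spec="s1", hosp="h1", res="r1", region="g1") -> ActorProfile:
    return ActorProfile(aid, specialty=spec, hospital=hosp,
                        residency_hospital=res, region=region)


def walk(wid: str, actors, start=0, gap=1, rvu=1.0) -> InformationWalk:
    return InformationWalk(
        wid, [Visit(a, start + i * gap, rvu) for i, a in enumerate(actors)]
    )


@pytest.fixture
def small_network() -> ReferralNetwork:
    """Seven actors over two regions / three hospitals with a mix of
    reciprocal and one-way referral edges."""
    actors = [
        make_profile("A", spec="cardio", hosp="h1", res="r1", region="east"),
        make_profile("B", spec="cardio", hosp="h1", res="r2", region="east"),
        make_profile("C", spec="surgery", hosp="h2", res="r1", region="east"),
        make_profile("D", spec="surgery", hosp="h2", res="r2", region="west"),
        make_profile("E", spec="radiology", hosp="h3", res="r3", region="west"),
        make_profile("F", spec="cardio", hosp="h3", res="r3", region="west"),
        make_profile("G", spec="surgery", hosp="h1", res="r1", region="east"),
    ]
    edges = {
        ("A", "B"): 4, ("B", "A"): 1,
        ("B", "C"): 5, ("C", "D"): 2,
        ("D", "E"): 3, ("E", "D"): 2,
        ("A", "C"): 1, ("F", "E"): 2,
        ("G", "A"): 1,
    }
    return ReferralNetwork(actors, edges)


@pytest.fixture
def fig1_corpus(small_network) -> WalkCorpus:
    """Three pairwise-overlapping walks: alpha shares C with beta and G with
    gamma; beta visits C,D,E,F and gamma visits E,F,G."""
    walks = [
        walk("alpha", ["A", "B", "C", "G"], start=0),
        walk("beta", ["C", "D", "E", "F"], start=1),
        walk("gamma", ["E", "F", "G"], start=2),
    ]
    return WalkCorpus(walks, small_network)


def random_walks(rng: np.random.Generator, network: ReferralNetwork, n: int,
                 min_len=2, max_len=6) -> list[InformationWalk]:
    ids = sorted(network.actors)
    out = []
    for k in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        actors = [ids[i] for i in rng.integers(0, len(ids), size=length)]
        out.append(walk(f"rw{k:03d}", actors, start=int(rng.integers(0, 50))))
    return out
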