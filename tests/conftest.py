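import numpy as np
import pytest

from rdscompare import ParticipantRecord, build_forest, generate_study, munich2017


def R(pid, rec=None, arm="RDS", d=2, complete=True, **attrs):
    """Shorthand participant record for fixtures."""
    return ParticipantRecord(
        participant_id=pid,
        recruiter_id=rec,
        arm=arm,
        network_size=d,
        complete=complete,
        attributes=attrs,
    )


@pytest.fixture(scope="session")
def munich_study():
    """One deterministic synthetic study under the munich2017 preset."""
    return generate_study(munich2017(random_seed=20170401))


@pytest.fixture(scope="session")
def branching_forest():
    """A 3-chain forest with enough depth for wave >= 2 analysis sets.

    Each seed recruits 2, each wave-1 participant recruits 2 (12 wave-2
    members total), alternating a binary attribute down the chains.
    """
    records = []
    for s in range(3):
        sid = f"s{s}"
        records.append(R(sid, grp="a" if s % 2 == 0 else "b", d=3 + s))
        for i in range(2):
            aid = f"{sid}w1{i}"
            records.append(R(aid, rec=sid, grp="a" if i == 0 else "b", d=2 + i))
            for j in range(2):
                bid = f"{aid}w2{j}"
                records.append(
                    R(bid, rec=aid, grp="a" if (i + j) % 2 == 0 else "b", d=1 + j)
                )
    return build_forest(records)
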