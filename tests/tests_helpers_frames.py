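"""Shared helpers for building small synthetic trajectories in tests."""

import numpy as np

from intmod.sampling import Frame, ModelState, Trajectory


def states_to_trajectory(model, states, scores):
    frames = [
        Frame(
            sweep=i,
            run=0,
            rot=st.rot.copy(),
            trans=st.trans.copy(),
            flex=st.flex.copy(),
            sigma=st.nuisances.sigma,
            psi=dict(st.nuisances.psi),
            score=float(s),
        )
        for i, (st, s) in enumerate(zip(states, scores))
    ]
    return Trajectory(run=0, save_interval=1, frames=frames)


def jittered_trajectory(model, rng, n, amplitude, base=None):
    base = base or ModelState.reference(model)
    states = []
    for _ in range(n):
        st = base.copy()
        for bi in model.mobile_rigid:
            st.trans[bi] = st.trans[bi] + rng.normal(scale=amplitude, size=3)
        if model.n_flex:
            st.flex = st.flex + rng.normal(scale=amplitude, size=st.flex.shape)
        states.append(st)
    return states_to_trajectory(model, states, rng.normal(size=n))
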