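"""Shared fixtures: swimmer bundles and cached torque pipelines."""

from __future__ import annotations

import numpy as np
import pytest

import swimtorque as st
from swimtorque.synthetic import fixture_suite


@pytest.fixture(scope="session")
def suite():
    """Eel and mackerel kinematics + bodies + momentum-conserving midlines."""
    return fixture_suite(ns=201, nt=256, n_periods=2)


class Pipeline:
    """Reactive-closure torque/power pipeline for one swimmer."""

    def __init__(self, fixture):
        self.body = fixture.body
        self.mid = fixture.midline
        self.force = st.reactive_force(self.mid, self.body)
        self.torque = st.torque_from_forces(self.force, self.mid, self.body)
        self.P_T = st.internal_power(self.torque, self.mid.kappadot)
        self.P_F = st.external_power(self.force, self.mid)
        self.budget = st.work_budget(self.P_T, self.mid.s, self.mid.t, P_F=self.P_F)


@pytest.fixture(scope="session")
def eel_pipeline(suite):
    return Pipeline(suite["eel"])


@pytest.fixture(scope="session")
def mackerel_pipeline(suite):
    return Pipeline(suite["mackerel"])


@pytest.fixture(scope="session")
def small_midline():
    """Coarse uniform-mass midline for cheap property tests."""
    spec = st.KinematicsSpec.mackerel()
    return st.make_midline(spec, ns=81, nt=64, n_periods=1)
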