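"""Maintenance: print the frozen trial-log values used by the regression
test (tests/test_protocols.py::test_golden_trial_log_regression).

Run manually after an intentional semantic change and update the test by
hand; the fixture is never regenerated implicitly.
"""
from autoshape import AgentConfig
from autoshape.protocols import Agent, run_trial

agent = Agent(AgentConfig(omega=0.8), [2024, 0])
for i in range(5):
    rec = run_trial(agent)
    print(i, [(s.value, a.value) for s, a in rec.actions],
          rec.lever_engaged, rec.magazine_engaged)
    print("  deltas", [round(e.delta, 12) for e in rec.rpes])
print("V:", {k.value: round(v, 12) for k, v in agent.fmf.V.items()})
print("Q(S_CS):", {k[1].value: round(agent.mb.Q[k], 12)
                   for k in agent.mb.Q if k[0] is k[0].__class__.S_CS})
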