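"""End-to-end match analysis: everything in one report.

Simulates a match with a planted pass-regularity correlation of -0.4,
runs io -> network -> positioning -> clustering -> statistics, and prints
the quantities a match report carries.
"""

from pitchnet import MatchConfig
from pitchnet.pipeline import run_match_analysis
from pitchnet.synthetic import make_match_fixture

config = MatchConfig(period_min=5.0, n_periods=2, seed=9)
fx = make_match_fixture(config, planted_rho=-0.4, seed=9)
report = run_match_analysis(fx.trajectories, fx.passes, config,
                            shots=fx.shots, goals=fx.goals,
                            voronoi_stride_s=5.0)

for team, ta in report.teams.items():
    corr = ta.correlations["directed"]
    print(f"team {team}: passes={ta.network.n_passes} shots={ta.shots} "
          f"goals={ta.goals} efficacy={ta.efficacy_pct}% "
          f"regularity classes k={ta.classification.k_selected}")
    print(f"  passes~ApEn (directed, n={corr.n}): r={corr.r:+.2f} "
          f"[{corr.ci90[0]:+.2f}; {corr.ci90[1]:+.2f}] "
          f"{corr.magnitude}, {corr.clarity}")

for name, eff in report.between.items():
    pct = "" if eff.pct_diff is None else \
        f" ({eff.pct_diff:+.1f}%; +/-{eff.pct_limit:.1f}%)"
    print(f"between-team {name}: d={eff.d:+.2f}{pct} "
          f"{eff.magnitude}, {eff.mbi}")
print("higher performance:", report.performance_ranking["higher"])

report.write("scratch/example_report")
print("tables + GraphML + JSON written to scratch/example_report/")
# The recovered negative correlation mirrors the planted structure: dyads
# that exchange more passes keep more regular (lower-ApEn) spacing.
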