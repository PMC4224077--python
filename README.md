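# coagswitch

Mechanistic simulation of the switch from warfarin to rivaroxaban.

Stopping a vitamin K antagonist (VKA) such as warfarin does not stop its
effect: the vitamin K-dependent clotting factors (II, VII, IX, X) and the
anticoagulant proteins C and S recover only on their turnover timescales
(5–60 h half-lives), so residual anticoagulation persists for days. A
patient started on rivaroxaban — a direct Factor Xa inhibitor — during
that window is exposed to *two* anticoagulant mechanisms at once, and the
combination is super-additive. `coagswitch` is a simulation toolkit for
clinical pharmacologists and modelers who want to reason quantitatively
about this transition: which rivaroxaban exposures are simultaneously safe
(no more anticoagulated than warfarin at INR 4–5 under a strong clotting
trigger) and efficacious (at least as anticoagulated as warfarin at INR
1.5–2 under a weak trigger) on each day after discontinuation.

## What is inside

* **Coagulation cascade** (`network`, `solver`): a mass-action ODE model
  of the extrinsic, intrinsic and common pathways (stoichiometric
  Hockin–Mann-class core: TF:VIIa tenase, TFPI and antithrombin
  regulation, prothrombinase, thrombin feedback on V/VIII/XI, protein C/S
  branch, fibrinogen conversion), with reversible, competitive binding of
  rivaroxaban to free and prothrombinase-bound Factor Xa. Clot time is
  the first crossing of a calibrated fibrin threshold.
* **Warfarin turnover** (`turnover`): effective R-/S-warfarin levels act
  through the synthesis pre-factor

      W = 1 / ((R + 3.25·S)² + 1)

  on the six vitamin K-dependent proteins, each following
  d[Pᵢ]/dt = (ln2/t½ᵢ)(kᵢ·W − [Pᵢ]). Discontinuation is the exponential
  decay of R and S with their own half-lives (45 h and 29 h for a typical
  Caucasian patient; S-half-lives scaled by the relative clearance
  469.4/654.3 for Japanese patients).
* **In-silico assays** (`assay`): PT test (TF 4·10⁻⁹ M), strong
  (10⁻¹¹ M) and weak (10⁻¹⁴ M) extrinsic triggers; INR = (PT/PT₀)^ISI
  with ISI 1.0; warfarin titration to a target INR by bracketed root
  finding.
* **Populations** (`populations`): Caucasian/Japanese profiles,
  fast/median/slow warfarin elimination, and the 24-profile
  factor-abnormality panel (fibrinogen, V, VIII, XI varied one at a time).
* **Nomograms** (`nomogram`, `pk`): time-resolved safety/efficacy
  exposure corridors, synergy-slope analysis, one-compartment PK overlay
  and dosing-schedule compliance checks.

## Worked example

```python
import coagswitch as cs

net = cs.get_network(cs.CAUCASIAN_MEDIAN)
print(cs.baseline_pt(net))                      # 11.999995  (drug-free PT, s)

w = cs.titrate_profile(net, 2.5)                # steady-state warfarin at INR 2.5
print(w.r_level)                                # 0.4000006  (effective racemic level)

from coagswitch.assay import run_assay, steady_state_levels
lev = steady_state_levels(w)
print(run_assay(cs.PT_TEST, net, vk_levels=lev).clot_time)   # 29.999976
print(run_assay(cs.PT_TEST, net, rivaroxaban_ugL=200).clot_time)  # 15.000037
print(run_assay(cs.PT_TEST, net, vk_levels=lev,
                rivaroxaban_ugL=200).clot_time)              # 54.552070
```

The last three numbers are the heart of the synergy story: warfarin alone
(INR 2.5) gives PT 30 s, rivaroxaban alone at 200 µg/L adds 3 s to the
12 s baseline — yet together they produce 54.6 s, far beyond the 33 s an
additive interaction would predict, because warfarin-suppressed
prothrombin no longer shields Factor Xa from the competitive inhibitor.

The corridor for this scenario (daily values, µg/L):

```python
sc = cs.SwitchScenario(2.5, cs.CAUCASIAN_MEDIAN)
corr = cs.compute_corridor(sc)          # hourly over 7 days, ~40 s on one CPU
```

| day | safety (high risk) | safety (normal) | efficacy (normal) | efficacy (high risk) |
|----:|----:|----:|----:|----:|
| 0 | 15.1 | 24.1 | 0.0 | 0.0 |
| 1 | 26.2 | 38.6 | 0.0 | 0.0 |
| 2 | 55.0 | 76.8 | 0.0 | 7.2 |
| 4 | 141.5 | 192.6 | 6.5 | 38.9 |
| 7 | 235.4 | 319.0 | 16.7 | 75.2 |

The window is narrow at discontinuation and widens toward the monotherapy
window (safety 300/406, efficacy 23.5/100 µg/L). Checking the bridging
schedule of 10 mg on day 1 followed by 20 mg once daily:

```python
sched = cs.DoseSchedule.bridging(10, 20)
cs.check_schedule(sched, corr, risk="high")["pass"]   # True
```

## Command line

```bash
coagswitch assay --start-inr 2.5            # clot times for the three triggers
coagswitch decay --start-inr 2.5            # factor recovery + INR time series
coagswitch corridor -c config.yaml --plot nomogram.png
coagswitch schedule-check -c config.yaml    # compliance report (JSON)
coagswitch panel                            # the 24 factor-abnormality corridors
```

Configuration is YAML (`scenario`, `assay`, `schedule`, `output` blocks);
defaults reproduce the Caucasian median start-INR-2.5 base case.

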