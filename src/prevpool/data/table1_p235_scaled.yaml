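# Desk-scale replication of the simulation scenario with survey-outcome
# prevalence 0.30 and record-outcome prevalence 0.35: population scaled from
# ten million to one million and the EHR from 100,000 to 20,000; survey size
# and linked count both 500 as in the full-scale study conditions.
scenario: table1_p235_scaled
N: 1000000
n1: 500
n2: 20000
overlap: 1.0
target_p1: 0.30
target_p2: 0.35
replicates: 100
estimators: [survey, ehr, mosteller]
seed: 20200406
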