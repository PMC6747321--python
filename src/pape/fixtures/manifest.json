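{
  "beacon_gap_example.csv": "35d623b8abe20dd469c021049e55fc52a0c9e464ec54efb219657a645389daa6",
  "table1_pollutants.csv": "c8a71db486e5d4e56f1a6978ecf0d60eeef9ee2f6058574cb10339b12ba361df",
  "table4_trace.csv": "f7efeb4ac9634e6b61d338515d9e7f940c952a0072cdfdbc3cc87b87b6ab3049",
  "table5_exposure.csv": "872069b889cc90961972a900c144ccb8f99435dcd6594cc626532509c78124a9",
  "table6_routes.csv": "1706b25a0216059201dba95eaec144b2b734bc8350aae2a56caa8dcb3925087c"
}
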