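# Cue-phrase rules signaling probable drug/therapy combinations.
# Numbering is stable; rule 9 is the "in combination with" cue.
- rule_id: 1
  pattern: "(?i)\\bcombined with\\b"
  label: combined with
- rule_id: 2
  pattern: "(?i)\\bcombination of\\b"
  label: combination of
- rule_id: 3
  pattern: "(?i)\\bcombination therapy (?:of|with)\\b"
  label: combination therapy
- rule_id: 4
  pattern: "(?i)\\bcombinations of\\b"
  label: combinations of
- rule_id: 5
  pattern: "(?i)\\bco-administration of\\b"
  label: co-administration of
- rule_id: 6
  pattern: "(?i)\\bco-administered with\\b"
  label: co-administered with
- rule_id: 7
  pattern: "(?i)\\bcoadministration of\\b"
  label: coadministration of
- rule_id: 8
  pattern: "(?i)\\bconcomitant(?:ly)? with\\b"
  label: concomitant with
- rule_id: 9
  pattern: "(?i)\\bin combination with\\b"
  label: in combination with
- rule_id: 10
  pattern: "(?i)\\bconcurrent(?:ly)? with\\b"
  label: concurrent with
- rule_id: 11
  pattern: "(?i)\\bin association with\\b"
  label: in association with
- rule_id: 12
  pattern: "(?i)\\bin conjunction with\\b"
  label: in conjunction with
- rule_id: 13
  pattern: "(?i)\\btogether with\\b"
  label: together with
- rule_id: 14
  pattern: "(?i)\\balong with\\b"
  label: along with
- rule_id: 15
  pattern: "(?i)\\badjuvant to\\b"
  label: adjuvant to
- rule_id: 16
  pattern: "(?i)\\bplus\\b"
  label: plus
- rule_id: 17
  pattern: "(?i)\\bfollowed by\\b"
  label: followed by
- rule_id: 18
  pattern: "(?i)\\bsynerg(?:y|ism|istic(?:ally)?) (?:with|between)\\b"
  label: synergy with
- rule_id: 19
  pattern: "(?i)\\badded to\\b"
  label: added to
- rule_id: 20
  pattern: "(?i)\\bco-treatment with\\b"
  label: co-treatment with
- rule_id: 21
  pattern: "(?i)\\bcotreatment with\\b"
  label: cotreatment with
- rule_id: 22
  pattern: "(?i)\\bin addition to\\b"
  label: in addition to
- rule_id: 23
  pattern: "(?i)\\balternating with\\b"
  label: alternating with
- rule_id: 24
  pattern: "(?i)\\bsequential(?:ly)? with\\b"
  label: sequential with
- rule_id: 25
  pattern: "(?i)\\bpaired with\\b"
  label: paired with
- rule_id: 26
  pattern: "(?i)\\bcoupled with\\b"
  label: coupled with
- rule_id: 27
  pattern: "(?i)\\bdual therapy (?:of|with)\\b"
  label: dual therapy
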