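# Screening instrument definitions, version 1.
#
# BHS4: short (four-item) Beck Hopelessness Scale. Items answered on a
#   0-3 Likert scale (0 not typical ... 3 very typical); total 0-12.
# BDI9: Hungarian short form of the Beck Depression Inventory (nine items),
#   answered on a 1-4 intensity scale (1 not typical ... 4 very typical);
#   total 9-36 with standard severity bands.
#
# Note: the published Hungarian short form prints identical wording for
# BDI items 4 and 6 even though the construct list names "work difficulty"
# as a distinct item.  The wording is carried verbatim as a documented
# erratum; scoring uses totals only, so it is unaffected.
version: 1
instruments:
  BHS4:
    n_items: 4
    item_min: 0
    item_max: 3
    total_min: 0
    total_max: 12
    items:
      - "My future seems dark to me"
      - "Things just won't work out the way I want them to"
      - "There's no use in really trying to get something I want because I probably won't get it"
      - "I feel that the future is hopeless and that things cannot improve"
    cutoffs:
      suicide_risk: 6        # total >= 6: suicide risk, referral indicated
      very_high_risk: 9      # total >= 9: very high risk annotation
  BDI9:
    n_items: 9
    item_min: 1
    item_max: 4
    total_min: 9
    total_max: 36
    items:
      - "I have lost all of my interest in other people"
      - "I can't make decisions at all anymore"
      - "I wake up several hours earlier than I used to and cannot get back to sleep"
      - "I am so worried about my physical problems that I cannot think of anything else"
      - "I am too tired to do anything"
      - "I am so worried about my physical problems that I cannot think of anything else"
      - "I feel the future is hopeless and that things cannot improve"
      - "I am dissatisfied or bored with everything"
      - "I feel guilty all of the time"
    bands:
      - {label: NO_DEPRESSION, lower: 9, upper: 13}
      - {label: MILD, lower: 14, upper: 18}
      - {label: MODERATE, lower: 19, upper: 24}
      - {label: SEVERE, lower: 25, upper: null}
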