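# Default S-GUS scoring configuration (stand-in subscore table).
# Override any item's levels/points; maxima must sum to 50 and item 12
# must score {agreement_value, 0}.
agreement_value: 3.2
items:
  - {item_id: 1, kind: single, levels: {yes: 2.0, no: 0.0}}
  - {item_id: 2, kind: single, levels: {yes: 2.0, no: 0.0}}
  - {item_id: 3, kind: single, levels: {yes: 2.0, no: 0.0}}
  - {item_id: 4, kind: single, levels: {yes: 3.0, no: 0.0}}
  - {item_id: 5, kind: single, levels: {yes: 3.0, no: 0.0}}
  - {item_id: 6, kind: single, levels: {yes: 3.0, no: 0.0}}
  - {item_id: 7, kind: single, levels: {yes: 3.0, no: 0.0}}
  - {item_id: 8, kind: single, levels: {yes: 3.0, no: 0.0}}
  - {item_id: 9, kind: single, levels: {yes: 3.0, no: 0.0}}
  - {item_id: 10, kind: difficulty, levels: {none: 10.0, mild: 6.6, moderate: 3.3, severe: 0.0}}
  - {item_id: 11, kind: difficulty, levels: {none: 12.8, mild: 8.5, moderate: 4.3, severe: 0.0}}
  - {item_id: 12, kind: agreement, levels: {yes: 3.2, no: 0.0}}
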