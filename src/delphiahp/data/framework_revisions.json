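[
 {
  "round": 1,
  "actions": [
   {
    "action": "delete",
    "id": "3.1.4",
    "note": "excluded after round 1"
   },
   {
    "action": "delete",
    "id": "3.2.3",
    "note": "excluded after round 1"
   },
   {
    "action": "delete",
    "id": "3.3.4",
    "note": "excluded after round 1"
   },
   {
    "action": "rename",
    "id": "1",
    "name": "Health Literacy",
    "note": "revised from 'Health problem solving'"
   },
   {
    "action": "rename",
    "id": "3",
    "name": "Digital competency",
    "note": "merge of 'Emotion and communication' and 'Digital protection' into one dimension"
   }
  ]
 },
 {
  "round": 2,
  "actions": [
   {
    "action": "delete",
    "id": "3.3.5",
    "note": "deleted after round 2"
   },
   {
    "action": "rename",
    "id": "3.2.2",
    "name": "Digital ethics and identity",
    "note": "revised from 'Internet etiquette'"
   }
  ]
 }
]
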