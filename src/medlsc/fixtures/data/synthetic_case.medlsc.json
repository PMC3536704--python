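{
  "format": "medlsc/1",
  "vocabulary": [
    {
      "name": "CFS",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "OTHER"
    },
    {
      "name": "DietModification",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "PROCEDURE"
    },
    {
      "name": "DocumentFatigue",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "SYMPTOM"
    },
    {
      "name": "DocumentMyalgia",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "SYMPTOM"
    },
    {
      "name": "Examination",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "PROCEDURE"
    },
    {
      "name": "GutSurgery",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "PROCEDURE"
    },
    {
      "name": "Probiotics",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "MEDICINE"
    },
    {
      "name": "ReportGutPains",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "SYMPTOM"
    },
    {
      "name": "ReportPain",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "SYMPTOM"
    },
    {
      "name": "ReportTiredness",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "SYMPTOM"
    },
    {
      "name": "SixMonthPeriod",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "ADMIN"
    },
    {
      "name": "reportImprovement",
      "kind": "SPECIFIC",
      "params": [],
      "tag": "OTHER"
    }
  ],
  "patients": [
    {
      "patient": "PATIENT:syntheticGutSurgeryCase",
      "meta": {
        "source": "synthetic conceptual case: CFS after gut surgery"
      },
      "charts": [
        {
          "name": "Development",
          "category": "DEVELOPMENT",
          "lifelines": [
            "DOCTOR:doctor",
            "PATIENT:syntheticGutSurgeryCase",
            "RECORD:syntheticGutSurgeryCase"
          ],
          "body": [
            {
              "event": "ReportGutPains",
              "source": "PATIENT:syntheticGutSurgeryCase",
              "target": "DOCTOR:doctor",
              "args": []
            },
            {
              "event": "Examination",
              "source": "DOCTOR:doctor",
              "target": "PATIENT:syntheticGutSurgeryCase",
              "args": []
            },
            {
              "event": "GutSurgery",
              "source": "DOCTOR:doctor",
              "target": "PATIENT:syntheticGutSurgeryCase",
              "args": []
            },
            {
              "event": "ReportTiredness",
              "source": "PATIENT:syntheticGutSurgeryCase",
              "target": "DOCTOR:doctor",
              "args": []
            },
            {
              "event": "ReportPain",
              "source": "PATIENT:syntheticGutSurgeryCase",
              "target": "DOCTOR:doctor",
              "args": []
            },
            {
              "event": "DocumentFatigue",
              "source": "DOCTOR:doctor",
              "target": "RECORD:syntheticGutSurgeryCase",
              "args": []
            },
            {
              "event": "DocumentMyalgia",
              "source": "DOCTOR:doctor",
              "target": "RECORD:syntheticGutSurgeryCase",
              "args": []
            },
            {
              "event": "CFS",
              "source": "DOCTOR:doctor",
              "target": "RECORD:syntheticGutSurgeryCase",
              "args": []
            }
          ],
          "activates": [
            [
              7,
              "Treatment"
            ]
          ]
        },
        {
          "name": "Treatment",
          "category": "TREATMENT",
          "lifelines": [
            "DOCTOR:doctor",
            "PATIENT:syntheticGutSurgeryCase",
            "RECORD:syntheticGutSurgeryCase"
          ],
          "body": [
            {
              "event": "DietModification",
              "source": "DOCTOR:doctor",
              "target": "PATIENT:syntheticGutSurgeryCase",
              "args": []
            },
            {
              "event": "Probiotics",
              "source": "DOCTOR:doctor",
              "target": "PATIENT:syntheticGutSurgeryCase",
              "args": []
            },
            {
              "event": "SixMonthPeriod",
              "source": "DOCTOR:doctor",
              "target": "RECORD:syntheticGutSurgeryCase",
              "args": []
            },
            {
              "event": "reportImprovement",
              "source": "PATIENT:syntheticGutSurgeryCase",
              "target": "DOCTOR:doctor",
              "args": []
            }
          ],
          "activates": []
        }
      ]
    }
  ]
}
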