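indicator_id,name,mean,sd,cv,weight
1,Health Literacy,5.00,0.00,0.00,0.4545
1.1,Health needs expression competency,5.00,0.00,0.00,0.2453
1.1.1,Health problem assessment,5.00,0.00,0.00,0.1635
1.1.2,Health needs expression,4.87,0.34,0.07,0.0818
1.2,Health decision making competency,4.87,0.34,0.07,0.1350
1.2.1,Personalized health decision making,4.80,0.40,0.08,0.1350
1.3,Health behavior change competency,4.80,0.40,0.08,0.0743
1.3.1,Adverse health behavior change,4.67,0.47,0.10,0.0743
2,Information literacy,5.00,0.00,0.00,0.4545
2.1,Health information acquisition competency,4.93,0.25,0.05,0.2121
2.1.1,Search tool selection,4.40,0.61,0.14,0.1591
2.1.2,Search strategy construction,4.20,0.65,0.16,0.0530
2.2,Health information screening competency,4.93,0.25,0.05,0.2121
2.2.1,Health information screening,4.87,0.34,0.07,0.0530
2.2.2,Health information reasoning evaluation,4.93,0.25,0.05,0.1061
2.2.3,Health information comparative evaluation,4.87,0.34,0.07,0.0530
2.3,Health information management competency,4.00,0.52,0.13,0.0303
2.3.1,Health information preservation/collection,4.07,0.57,0.14,0.0202
2.3.2,Health information organization,4.00,0.52,0.13,0.0101
3,Digital competency,4.33,0.47,0.11,0.0909
3.1,Digital interaction competency,4.13,0.81,0.19,0.0171
3.1.1,Health activity participation,4.27,0.68,0.16,0.0085
3.1.2,Health data sharing,4.20,0.40,0.10,0.0053
3.1.3,Health problem discussion,4.13,0.62,0.15,0.0034
3.2,Digital emotional competency,3.80,0.65,0.17,0.0074
3.2.1,Emotion recognition and expression,4.00,0.63,0.16,0.0055
3.2.2,Digital ethics and identity,3.80,0.54,0.14,0.0018
3.3,Digital protection competency,4.73,0.57,0.12,0.0664
3.3.1,Personal information protection,4.60,0.49,0.11,0.0371
3.3.2,Digital media protection,4.47,0.50,0.11,0.0212
3.3.3,Physical and mental health protection,4.20,0.40,0.10,0.0081
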