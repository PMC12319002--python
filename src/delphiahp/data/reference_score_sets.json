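{
"1": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5
],
"1.1": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5
],
"1.1.1": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5
],
"1.1.2": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4,
4
],
"1.2": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4,
4
],
"1.2.1": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4,
4,
4
],
"1.3": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4,
4,
4
],
"1.3.1": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4,
4,
4,
4,
4
],
"2": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5
],
"2.1": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4
],
"2.1.1": [
5,
5,
5,
5,
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
3
],
"2.1.2": [
5,
5,
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
3,
3
],
"2.2": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4
],
"2.2.1": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4,
4
],
"2.2.2": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4
],
"2.2.3": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4,
4
],
"2.3": [
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
3,
3
],
"2.3.1": [
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
3,
3
],
"2.3.2": [
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
3,
3
],
"3": [
5,
5,
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4
],
"3.1": [
5,
5,
5,
5,
5,
5,
4,
4,
4,
4,
4,
3,
3,
3,
3
],
"3.1.1": [
5,
5,
5,
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
3,
3
],
"3.1.2": [
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4
],
"3.1.3": [
5,
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
4,
3,
3
],
"3.2": [
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
3,
3,
3,
3,
3
],
"3.2.1": [
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
4,
3,
3,
3
],
"3.2.2": [
5,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
3,
3,
3,
3
],
"3.3": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
5,
4,
4,
3
],
"3.3.1": [
5,
5,
5,
5,
5,
5,
5,
5,
5,
4,
4,
4,
4,
4,
4
],
"3.3.2": [
5,
5,
5,
5,
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
4
],
"3.3.3": [
5,
5,
5,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4,
4
]
}
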