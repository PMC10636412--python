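name: synthetic-128
labels:
- E1
- E2
- E3
- E4
- E5
- E6
- E7
- E8
- E9
- E10
- E11
- E12
- E13
- E14
- E15
- E16
- E17
- E18
- E19
- E20
- E21
- E22
- E23
- E24
- E25
- E26
- E27
- E28
- E29
- E30
- E31
- E32
- E33
- E34
- E35
- E36
- E37
- E38
- E39
- E40
- E41
- E42
- E43
- E44
- E45
- E46
- E47
- E48
- E49
- E50
- E51
- E52
- E53
- E54
- E55
- E56
- E57
- E58
- E59
- E60
- E61
- E62
- E63
- E64
- E65
- E66
- E67
- E68
- E69
- E70
- E71
- E72
- E73
- E74
- E75
- E76
- E77
- E78
- E79
- E80
- E81
- E82
- E83
- E84
- E85
- E86
- E87
- E88
- E89
- E90
- E91
- E92
- E93
- E94
- E95
- E96
- E97
- E98
- E99
- E100
- E101
- E102
- E103
- E104
- E105
- E106
- E107
- E108
- E109
- E110
- E111
- E112
- E113
- E114
- E115
- E116
- E117
- E118
- E119
- E120
- E121
- E122
- E123
- E124
- E125
- E126
- E127
- E128
clusters:
  left:
  - E37
  - E20
  - E21
  - E22
  - E36
  - E38
  - E53
  right:
  - E44
  - E29
  - E28
  - E27
  - E45
  - E43
  - E60
adjacency:
  E1:
  - E17
  - E2
  E2:
  - E18
  - E1
  - E3
  E3:
  - E19
  - E2
  - E4
  E4:
  - E20
  - E3
  - E5
  E5:
  - E21
  - E4
  - E6
  E6:
  - E22
  - E5
  - E7
  E7:
  - E23
  - E6
  - E8
  E8:
  - E24
  - E7
  - E9
  E9:
  - E25
  - E8
  - E10
  E10:
  - E26
  - E9
  - E11
  E11:
  - E27
  - E10
  - E12
  E12:
  - E28
  - E11
  - E13
  E13:
  - E29
  - E12
  - E14
  E14:
  - E30
  - E13
  - E15
  E15:
  - E31
  - E14
  - E16
  E16:
  - E32
  - E15
  E17:
  - E1
  - E33
  - E18
  E18:
  - E2
  - E34
  - E17
  - E19
  E19:
  - E3
  - E35
  - E18
  - E20
  E20:
  - E4
  - E36
  - E19
  - E21
  E21:
  - E5
  - E37
  - E20
  - E22
  E22:
  - E6
  - E38
  - E21
  - E23
  E23:
  - E7
  - E39
  - E22
  - E24
  E24:
  - E8
  - E40
  - E23
  - E25
  E25:
  - E9
  - E41
  - E24
  - E26
  E26:
  - E10
  - E42
  - E25
  - E27
  E27:
  - E11
  - E43
  - E26
  - E28
  E28:
  - E12
  - E44
  - E27
  - E29
  E29:
  - E13
  - E45
  - E28
  - E30
  E30:
  - E14
  - E46
  - E29
  - E31
  E31:
  - E15
  - E47
  - E30
  - E32
  E32:
  - E16
  - E48
  - E31
  E33:
  - E17
  - E49
  - E34
  E34:
  - E18
  - E50
  - E33
  - E35
  E35:
  - E19
  - E51
  - E34
  - E36
  E36:
  - E20
  - E52
  - E35
  - E37
  E37:
  - E21
  - E53
  - E36
  - E38
  E38:
  - E22
  - E54
  - E37
  - E39
  E39:
  - E23
  - E55
  - E38
  - E40
  E40:
  - E24
  - E56
  - E39
  - E41
  E41:
  - E25
  - E57
  - E40
  - E42
  E42:
  - E26
  - E58
  - E41
  - E43
  E43:
  - E27
  - E59
  - E42
  - E44
  E44:
  - E28
  - E60
  - E43
  - E45
  E45:
  - E29
  - E61
  - E44
  - E46
  E46:
  - E30
  - E62
  - E45
  - E47
  E47:
  - E31
  - E63
  - E46
  - E48
  E48:
  - E32
  - E64
  - E47
  E49:
  - E33
  - E65
  - E50
  E50:
  - E34
  - E66
  - E49
  - E51
  E51:
  - E35
  - E67
  - E50
  - E52
  E52:
  - E36
  - E68
  - E51
  - E53
  E53:
  - E37
  - E69
  - E52
  - E54
  E54:
  - E38
  - E70
  - E53
  - E55
  E55:
  - E39
  - E71
  - E54
  - E56
  E56:
  - E40
  - E72
  - E55
  - E57
  E57:
  - E41
  - E73
  - E56
  - E58
  E58:
  - E42
  - E74
  - E57
  - E59
  E59:
  - E43
  - E75
  - E58
  - E60
  E60:
  - E44
  - E76
  - E59
  - E61
  E61:
  - E45
  - E77
  - E60
  - E62
  E62:
  - E46
  - E78
  - E61
  - E63
  E63:
  - E47
  - E79
  - E62
  - E64
  E64:
  - E48
  - E80
  - E63
  E65:
  - E49
  - E81
  - E66
  E66:
  - E50
  - E82
  - E65
  - E67
  E67:
  - E51
  - E83
  - E66
  - E68
  E68:
  - E52
  - E84
  - E67
  - E69
  E69:
  - E53
  - E85
  - E68
  - E70
  E70:
  - E54
  - E86
  - E69
  - E71
  E71:
  - E55
  - E87
  - E70
  - E72
  E72:
  - E56
  - E88
  - E71
  - E73
  E73:
  - E57
  - E89
  - E72
  - E74
  E74:
  - E58
  - E90
  - E73
  - E75
  E75:
  - E59
  - E91
  - E74
  - E76
  E76:
  - E60
  - E92
  - E75
  - E77
  E77:
  - E61
  - E93
  - E76
  - E78
  E78:
  - E62
  - E94
  - E77
  - E79
  E79:
  - E63
  - E95
  - E78
  - E80
  E80:
  - E64
  - E96
  - E79
  E81:
  - E65
  - E97
  - E82
  E82:
  - E66
  - E98
  - E81
  - E83
  E83:
  - E67
  - E99
  - E82
  - E84
  E84:
  - E68
  - E100
  - E83
  - E85
  E85:
  - E69
  - E101
  - E84
  - E86
  E86:
  - E70
  - E102
  - E85
  - E87
  E87:
  - E71
  - E103
  - E86
  - E88
  E88:
  - E72
  - E104
  - E87
  - E89
  E89:
  - E73
  - E105
  - E88
  - E90
  E90:
  - E74
  - E106
  - E89
  - E91
  E91:
  - E75
  - E107
  - E90
  - E92
  E92:
  - E76
  - E108
  - E91
  - E93
  E93:
  - E77
  - E109
  - E92
  - E94
  E94:
  - E78
  - E110
  - E93
  - E95
  E95:
  - E79
  - E111
  - E94
  - E96
  E96:
  - E80
  - E112
  - E95
  E97:
  - E81
  - E113
  - E98
  E98:
  - E82
  - E114
  - E97
  - E99
  E99:
  - E83
  - E115
  - E98
  - E100
  E100:
  - E84
  - E116
  - E99
  - E101
  E101:
  - E85
  - E117
  - E100
  - E102
  E102:
  - E86
  - E118
  - E101
  - E103
  E103:
  - E87
  - E119
  - E102
  - E104
  E104:
  - E88
  - E120
  - E103
  - E105
  E105:
  - E89
  - E121
  - E104
  - E106
  E106:
  - E90
  - E122
  - E105
  - E107
  E107:
  - E91
  - E123
  - E106
  - E108
  E108:
  - E92
  - E124
  - E107
  - E109
  E109:
  - E93
  - E125
  - E108
  - E110
  E110:
  - E94
  - E126
  - E109
  - E111
  E111:
  - E95
  - E127
  - E110
  - E112
  E112:
  - E96
  - E128
  - E111
  E113:
  - E97
  - E114
  E114:
  - E98
  - E113
  - E115
  E115:
  - E99
  - E114
  - E116
  E116:
  - E100
  - E115
  - E117
  E117:
  - E101
  - E116
  - E118
  E118:
  - E102
  - E117
  - E119
  E119:
  - E103
  - E118
  - E120
  E120:
  - E104
  - E119
  - E121
  E121:
  - E105
  - E120
  - E122
  E122:
  - E106
  - E121
  - E123
  E123:
  - E107
  - E122
  - E124
  E124:
  - E108
  - E123
  - E125
  E125:
  - E109
  - E124
  - E126
  E126:
  - E110
  - E125
  - E127
  E127:
  - E111
  - E126
  - E128
  E128:
  - E112
  - E127
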